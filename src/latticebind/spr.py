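"""Equilibrium SPR fitting and ReDCaT screening statistics.

Two workflows share the response-to-density transform of
:mod:`latticebind.lattice`:

* **Isotherm fitting** — a dilution series of protein injected over an
  immobilized duplex gives (L, R_eq) pairs.  Each response is converted to an
  observed binding density and the finite-lattice isotherm is fitted by
  least squares in v, minimizing over log10(Ka) with L-BFGS-B for every
  integer candidate site size n; the (n, Kd) pair with the smallest residual
  sum of squares wins (ties go to the smaller n).

* **Segment screening** — a genome region tiled into overlapping duplex
  segments is probed at a single protein concentration.  Per-segment binding
  levels are normalized to the amount of DNA annealed in that cycle
  (proteins per DNA), optionally drift-corrected against a standard sequence
  re-measured through the run, and compared by one-way ANOVA with Tukey HSD
  post-hoc tests.  Segments more than one standard deviation above the grand
  mean are flagged as candidate enhanced-affinity sites.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .lattice import LatticeModel, MassContext, response_to_density, solve_binding_density

__all__ = [
    "SPRRecord",
    "FitResult",
    "FittingError",
    "ScreenSegment",
    "AnovaResult",
    "fit_equilibrium",
    "screen_normalize",
    "drift_correct",
    "screen_anova",
    "tukey_hsd",
    "flag_above_average",
    "FlagResult",
]

log = logging.getLogger(__name__)

LOG10_KA_BOUNDS = (0.0, 12.0)


class FittingError(RuntimeError):
    """No candidate site size produced a converged fit."""


@dataclass(frozen=True)
class SPRRecord:
    """One equilibrium injection: concentration (M), response (RU), replicate."""

    concentration: float
    R_eq: float
    replicate: str = "1"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.concentration) and self.concentration > 0):
            raise ValueError(f"injected concentration must be finite and > 0, got {self.concentration}")
        if not math.isfinite(self.R_eq):
            raise ValueError("equilibrium response must be finite")


@dataclass(frozen=True)
class FitResult:
    """Best-fit site size and affinity with per-candidate diagnostics."""

    n_best: int
    Kd: float  # molar
    Kd_se: float  # molar, linearized standard error
    rss: float  # residual sum of squares in v
    s_reg: float  # standard error of regression, sqrt(rss / (m - 1))
    per_n_table: pd.DataFrame  # columns: n, Ka, Kd, Kd_se, rss, s_reg, converged


def _coerce_records(records) -> list[SPRRecord]:
    if isinstance(records, pd.DataFrame):
        return [
            SPRRecord(
                concentration=float(r["concentration_M"]),
                R_eq=float(r["R_eq_RU"]),
                replicate=str(r.get("replicate", "1")),
            )
            for _, r in records.iterrows()
        ]
    return list(records)


def _ssr_and_model(log10_ka, n: int, L: np.ndarray, v_obs: np.ndarray, N: int) -> float:
    log10_ka = float(np.asarray(log10_ka).ravel()[0])
    model = LatticeModel(Ka=10.0**log10_ka, n=n, N=N)
    v_model = solve_binding_density(L, model)
    resid = v_obs - v_model
    return float(resid @ resid)


def fit_equilibrium(
    records,
    ctx: MassContext,
    n_grid: Sequence[int] = range(1, 11),
) -> FitResult:
    """Fit (n, Kd) of the finite-lattice isotherm to an equilibrium panel.

    Parameters
    ----------
    records
        Sequence of :class:`SPRRecord` or a DataFrame with columns
        ``concentration_M``, ``R_eq_RU`` (and optionally ``replicate``).
    ctx
        Masses, duplex length and immobilization response used to transform
        responses into observed densities.
    n_grid
        Integer candidate site sizes; each must lie in ``[1, ctx.N]``.

    For each n the residual sum of squares in v is minimized over
    ``log10(Ka) in [0, 12]`` by L-BFGS-B seeded from a coarse grid scan.
    ``s_reg = sqrt(rss / (m - 1))`` with m data points and one free
    parameter per candidate.  Requires >= 4 distinct concentrations.
    """
    recs = _coerce_records(records)
    n_grid = list(n_grid)
    if not n_grid:
        raise ValueError("n_grid is empty")
    for n in n_grid:
        if not 1 <= n <= ctx.N:
            raise ValueError(f"candidate site size {n} outside [1, N={ctx.N}]")
    L = np.array([r.concentration for r in recs])
    if len(np.unique(L)) < 4:
        raise ValueError(
            f"need >= 4 distinct concentrations to constrain (n, Kd); got {len(np.unique(L))}"
        )
    v_obs = response_to_density(np.array([r.R_eq for r in recs]), ctx)
    m = len(recs)

    coarse = np.linspace(*LOG10_KA_BOUNDS, 25)
    rows = []
    for n in n_grid:
        ssr_coarse = [_ssr_and_model(x, n, L, v_obs, ctx.N) for x in coarse]
        x0 = coarse[int(np.argmin(ssr_coarse))]
        res = optimize.minimize(
            _ssr_and_model,
            x0=[x0],
            args=(n, L, v_obs, ctx.N),
            method="L-BFGS-B",
            bounds=[LOG10_KA_BOUNDS],
        )
        ka = float(10.0 ** res.x[0])
        rss = float(res.fun)
        s_reg = math.sqrt(rss / (m - 1))
        kd_se = _kd_standard_error(ka, n, L, v_obs, ctx.N, rss, m)
        if not res.success:
            log.warning("L-BFGS-B did not converge for n=%d: %s", n, res.message)
        rows.append(
            {
                "n": n,
                "Ka": ka,
                "Kd": 1.0 / ka,
                "Kd_se": kd_se,
                "rss": rss,
                "s_reg": s_reg,
                "converged": bool(res.success),
            }
        )
    table = pd.DataFrame(rows)
    ok = table[table["converged"]]
    if ok.empty:
        raise FittingError("optimizer failed to converge for every candidate site size")
    best = ok.sort_values(["rss", "n"], kind="stable").iloc[0]
    return FitResult(
        n_best=int(best["n"]),
        Kd=float(best["Kd"]),
        Kd_se=float(best["Kd_se"]),
        rss=float(best["rss"]),
        s_reg=float(best["s_reg"]),
        per_n_table=table,
    )


def _kd_standard_error(
    ka: float, n: int, L: np.ndarray, v_obs: np.ndarray, N: int, rss: float, m: int
) -> float:
    """Linearized SE of Kd: from the Jacobian of v_model w.r.t. Ka."""
    h = 1e-4  # relative step
    model_hi = LatticeModel(Ka=ka * (1 + h), n=n, N=N)
    model_lo = LatticeModel(Ka=ka * (1 - h), n=n, N=N)
    jac = (solve_binding_density(L, model_hi) - solve_binding_density(L, model_lo)) / (2 * h * ka)
    jtj = float(jac @ jac)
    if jtj <= 0 or m <= 1:
        return float("nan")
    var_ka = rss / (m - 1) / jtj
    return math.sqrt(var_ka) / ka**2  # |dKd/dKa| = 1/Ka^2


# ---------------------------------------------------------------------------
# ReDCaT screening
# ---------------------------------------------------------------------------


@dataclass
class ScreenSegment:
    """One tiled genome segment measured in one screening cycle.

    ``position`` is the 0-based offset of the segment start relative to the
    first base of the small-terminase start codon (signed).  ``responses``
    are replicate double-referenced equilibrium responses (RU); ``R_L`` is
    the annealed-duplex response for this cycle.  Densities (proteins per
    DNA, and per bp) are populated by :func:`screen_normalize`.
    """

    segment_id: str
    genome: str
    position: int
    R_L: float
    responses: list[float]
    cycle: int | None = None
    density: float | None = None  # mean proteins per DNA
    density_per_bp: float | None = None
    replicate_densities: list[float] = field(default_factory=list)


def screen_normalize(
    segments: Sequence[ScreenSegment],
    ctx: MassContext | Mapping[str, MassContext],
) -> list[ScreenSegment]:
    """Populate per-segment binding densities (proteins per DNA).

    Each replicate response is normalized by that cycle's annealed-DNA
    response (the segment's own ``R_L``) through the mass-ratio transform,
    then scaled by the duplex length to give proteins per DNA.  Negative
    double-referenced densities are clamped to zero for reporting (with a
    logged warning).  Segments without a usable ``R_L`` are skipped.

    ``ctx`` may be a single :class:`MassContext` applied to every segment or
    a mapping from segment_id to contexts (segments of different lengths).
    """
    out: list[ScreenSegment] = []
    for seg in segments:
        base = ctx[seg.segment_id] if isinstance(ctx, Mapping) else ctx
        if seg.R_L is None or not math.isfinite(seg.R_L) or seg.R_L <= 0:
            log.warning("segment %s skipped: missing or invalid R_L (%r)", seg.segment_id, seg.R_L)
            continue
        if not seg.responses:
            log.warning("segment %s skipped: no replicate responses", seg.segment_id)
            continue
        eff = replace(base, R_L=seg.R_L)
        dens = [response_to_density(r, eff) * eff.N for r in seg.responses]
        clamped = [max(d, 0.0) for d in dens]
        if any(d < 0 for d in dens):
            log.warning(
                "segment %s: %d negative double-referenced densities clamped to 0",
                seg.segment_id,
                sum(d < 0 for d in dens),
            )
        seg = replace_fields(
            seg,
            replicate_densities=clamped,
            density=float(np.mean(clamped)),
            density_per_bp=float(np.mean(clamped)) / eff.N,
        )
        out.append(seg)
    return out


def replace_fields(seg: ScreenSegment, **kw) -> ScreenSegment:
    """Shallow copy of a segment with selected fields replaced."""
    data = {**seg.__dict__, **kw}
    data.pop("replicate_densities", None)
    new = ScreenSegment(
        segment_id=data["segment_id"],
        genome=data["genome"],
        position=data["position"],
        R_L=data["R_L"],
        responses=list(data["responses"]),
        cycle=data["cycle"],
        density=data["density"],
        density_per_bp=data["density_per_bp"],
    )
    new.replicate_densities = list(kw.get("replicate_densities", seg.replicate_densities))
    return new


def drift_correct(
    segments: Sequence[ScreenSegment], standard_id: str
) -> list[ScreenSegment]:
    """Rescale densities against a standard sequence repeated through the run.

    Instrument drift over a long screening run is controlled by re-measuring
    one standard duplex at intervals.  Every segment's densities are scaled
    by ``grand_mean(standard) / nearest_standard_density``, where "nearest"
    is by cycle index (list order if cycles are absent); standard occurrences
    themselves therefore map onto the grand mean.  With fewer than two
    standard occurrences the panel passes through unchanged with a warning.
    """
    segs = list(segments)
    order = [s.cycle if s.cycle is not None else i for i, s in enumerate(segs)]
    std_idx = [i for i, s in enumerate(segs) if s.segment_id == standard_id]
    if len(std_idx) < 2:
        log.warning(
            "drift correction skipped: %d occurrence(s) of standard %r (need >= 2)",
            len(std_idx),
            standard_id,
        )
        return [replace_fields(s) for s in segs]
    std_densities = {i: segs[i].density for i in std_idx}
    if any(d is None for d in std_densities.values()):
        raise ValueError("densities must be populated (screen_normalize) before drift correction")
    grand = float(np.mean(list(std_densities.values())))
    out = []
    for i, seg in enumerate(segs):
        nearest = min(std_idx, key=lambda j: (abs(order[j] - order[i]), order[j]))
        ref = std_densities[nearest]
        factor = grand / ref if ref > 0 else 1.0
        out.append(
            replace_fields(
                seg,
                density=seg.density * factor,
                density_per_bp=seg.density_per_bp * factor,
                replicate_densities=[d * factor for d in seg.replicate_densities],
            )
        )
    return out


class AnovaResult(NamedTuple):
    F: float
    df_between: int
    df_within: int
    p_value: float


def _group_densities(
    segments: Sequence[ScreenSegment], use_replicates: bool
) -> dict[str, list[float]]:
    """Replicate densities (or per-cycle means) grouped by segment id."""
    groups: dict[str, list[float]] = {}
    for seg in segments:
        if not seg.replicate_densities:
            raise ValueError(f"segment {seg.segment_id} has no densities; run screen_normalize first")
        vals = seg.replicate_densities if use_replicates else [float(np.mean(seg.replicate_densities))]
        groups.setdefault(seg.segment_id, []).extend(vals)
    return groups


def screen_anova(
    segments: Sequence[ScreenSegment] | Mapping[str, Sequence[float]],
    use_replicates: bool = True,
) -> AnovaResult:
    """One-way fixed-effects ANOVA over per-segment binding densities.

    ``use_replicates=True`` (default) treats every replicate density as an
    observation; ``False`` collapses each cycle to its mean first, so
    segments must then appear in multiple cycles.  Groups contributing a
    single observation are excluded with a warning.
    """
    if isinstance(segments, Mapping):
        groups = {k: list(v) for k, v in segments.items()}
    else:
        groups = _group_densities(segments, use_replicates)
    kept = {k: v for k, v in groups.items() if len(v) >= 2}
    for k in groups.keys() - kept.keys():
        log.warning("group %s excluded from ANOVA: fewer than 2 observations", k)
    if len(kept) < 2:
        raise ValueError(f"ANOVA needs >= 2 groups with >= 2 observations, got {len(kept)}")
    arrays = [np.asarray(v, dtype=float) for v in kept.values()]
    f, p = stats.f_oneway(*arrays)
    df_between = len(arrays) - 1
    df_within = sum(len(a) for a in arrays) - len(arrays)
    # all-identical observations: scipy returns nan with a constant-input warning
    if math.isnan(f) and np.ptp(np.concatenate(arrays)) == 0:
        f, p = 0.0, 1.0
    return AnovaResult(F=float(f), df_between=df_between, df_within=df_within, p_value=float(p))


def tukey_hsd(
    segments: Sequence[ScreenSegment] | Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    use_replicates: bool = True,
) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons of segment binding densities.

    Returns one row per unordered pair with columns ``group1``, ``group2``,
    ``mean_diff``, ``p_value``, ``q_crit`` (studentized-range critical value
    at ``alpha``) and ``significant``.  Critical values come from the
    studentized range distribution, never from a hard-coded table.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if isinstance(segments, Mapping):
        groups = {k: list(v) for k, v in segments.items()}
    else:
        groups = _group_densities(segments, use_replicates)
    kept = {k: np.asarray(v, dtype=float) for k, v in groups.items() if len(v) >= 2}
    for k in groups.keys() - kept.keys():
        log.warning("group %s excluded from Tukey HSD: fewer than 2 observations", k)
    if len(kept) < 2:
        raise ValueError("Tukey HSD needs >= 2 groups with >= 2 observations")
    names = list(kept)
    arrays = [kept[k] for k in names]
    res = stats.tukey_hsd(*arrays)
    df_within = sum(len(a) for a in arrays) - len(arrays)
    q_crit = float(stats.studentized_range.ppf(1 - alpha, len(arrays), df_within))
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p = float(res.pvalue[i, j])
            rows.append(
                {
                    "group1": names[i],
                    "group2": names[j],
                    "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                    "p_value": p,
                    "q_crit": q_crit,
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)


class FlagResult(NamedTuple):
    flagged: list[str]  # segment ids strictly above the threshold
    grand_mean: float
    sd: float
    threshold: float


def flag_above_average(segments: Sequence[ScreenSegment]) -> FlagResult:
    """Segments whose mean density exceeds the grand mean by more than 1 SD.

    The grand mean and sample standard deviation are computed over segment
    mean densities (one value per segment occurrence).  The comparison is
    strict.
    """
    segs = list(segments)
    if len(segs) < 3:
        raise ValueError(f"need >= 3 segments, got {len(segs)}")
    if any(s.density is None for s in segs):
        raise ValueError("densities must be populated (screen_normalize) first")
    means = np.array([s.density for s in segs])
    grand = float(means.mean())
    sd = float(means.std(ddof=1))
    threshold = grand + sd
    flagged = [s.segment_id for s in segs if s.density > threshold]
    return FlagResult(flagged=flagged, grand_mean=grand, sd=sd, threshold=threshold)
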