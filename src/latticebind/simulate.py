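"""Seeded generators for every input table the analysis pipeline consumes.

Each generator is the exact forward model of its consuming analysis plus
configurable noise, with the ground truth recorded alongside, so parameter
recovery can be tested end to end:

* :func:`gen_spr_panel` — an equilibrium dilution-series panel from the
  finite-lattice isotherm (default: 16 two-fold dilutions from 1500 uM down
  to ~0.046 uM, in triplicate — the concentration design used for weak
  millimolar binders, which cannot be saturated).
* :func:`gen_redcat_panel` — a tiled-segment screen at a single probe
  concentration (default 20 uM, 32 segments over two genome labels, 30-bp
  windows stepping 25 bp), with optional planted enhanced-affinity segments,
  a repeated standard sequence and optional linear instrument drift.
* :func:`gen_auc_species` — sedimentation coefficients of protein-DNA
  complexes with planted stoichiometries, via the inverse Svedberg relation
  with per-state mass-weighted partial specific volumes.
* :func:`gen_csp` — a fast-exchange HSQC titration: observed peak = free
  position + fraction_bound * delta_max on planted surface residues, noise
  only elsewhere.

Every generator draws from its own seed-derived stream
(``default_rng([seed, stream_id])``), so adding one call never perturbs the
output of another.  Identical configurations give bit-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .auc import (
    VBAR_DNA,
    VBAR_PROTEIN_DEFAULT,
    WATER_20C,
    BufferConditions,
    sedimentation_from_mass,
    weighted_vbar,
)
from .lattice import LatticeModel, MassContext, density_to_response, solve_binding_density
from .spr import ScreenSegment, SPRRecord

__all__ = ["SimConfig", "gen_spr_panel", "gen_redcat_panel", "gen_auc_species", "gen_csp"]

# fixed per-generator stream ids
_STREAM_SPR = 101
_STREAM_REDCAT = 202
_STREAM_AUC = 303
_STREAM_CSP = 404


@dataclass(frozen=True)
class SimConfig:
    """Design parameters and noise levels for the synthetic generators.

    Defaults reproduce the experimental designs the analyses assume: a
    two-fold SPR dilution series 1500 uM down to ~0.046 uM in triplicate; a
    32-segment screen probed at 20 uM; 2% coefficient of variation on
    sedimentation coefficients; 0.005 ppm background scatter on NMR peaks.
    All noise SDs/CVs must be >= 0; identical configs give identical output.
    """

    seed: int = 0
    # SPR equilibrium panel
    conc_max: float = 1.5e-3  # M
    n_dilutions: int = 16
    dilution_factor: float = 2.0
    replicates: int = 3
    spr_additive_sd_ru: float = 1.0
    spr_multiplicative_cv: float = 0.01
    # ReDCaT screen
    screen_conc: float = 2.0e-5  # M
    segment_window: int = 30  # bp
    segment_step: int = 25  # bp
    r_l_ru: float = 450.0
    # AUC
    auc_s_cv: float = 0.02
    # CSP
    csp_background_sd_ppm: float = 0.005
    protein_conc: float = 3.0e-4  # M, NMR sample

    def __post_init__(self) -> None:
        for name in ("spr_additive_sd_ru", "spr_multiplicative_cv", "auc_s_cv", "csp_background_sd_ppm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_dilutions < 1 or self.replicates < 1:
            raise ValueError("n_dilutions and replicates must be >= 1")
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must be > 1")


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def concentration_series(cfg: SimConfig) -> np.ndarray:
    """Injected concentrations (M), descending from conc_max."""
    return cfg.conc_max / cfg.dilution_factor ** np.arange(cfg.n_dilutions)


def gen_spr_panel(
    model: LatticeModel, ctx: MassContext, cfg: SimConfig = SimConfig()
) -> pd.DataFrame:
    """Simulate an equilibrium SPR dilution-series panel.

    For every concentration and replicate, the noise-free response is
    ``density_to_response(solve_binding_density(L, model))``; additive
    (RU) and multiplicative (CV) Gaussian noise are then applied.  Returns a
    DataFrame with columns ``concentration_M``, ``R_eq_RU``, ``replicate``
    and the generating truth in ``.attrs["truth"]``.
    """
    rng = _rng(cfg, _STREAM_SPR)
    L = concentration_series(cfg)
    v = solve_binding_density(L, model)
    r_true = density_to_response(v, ctx)
    rows = []
    for rep in range(1, cfg.replicates + 1):
        noise = cfg.spr_additive_sd_ru * rng.standard_normal(len(L))
        mult = 1.0 + cfg.spr_multiplicative_cv * rng.standard_normal(len(L))
        r_obs = r_true * mult + noise
        for conc, r in zip(L, r_obs):
            rows.append({"concentration_M": conc, "R_eq_RU": r, "replicate": str(rep)})
    out = pd.DataFrame(rows)
    out.attrs["truth"] = {"n": model.n, "Kd": model.Kd, "Ka": model.Ka, "N": model.N}
    return out


def spr_records(panel: pd.DataFrame) -> list[SPRRecord]:
    """Convert a generated panel to :class:`SPRRecord` objects."""
    return [
        SPRRecord(concentration=float(r["concentration_M"]), R_eq=float(r["R_eq_RU"]), replicate=str(r["replicate"]))
        for _, r in panel.iterrows()
    ]


def gen_redcat_panel(
    n_segments: int,
    baseline: LatticeModel,
    enhanced: dict[str, float] | None = None,
    cfg: SimConfig = SimConfig(),
    ctx: MassContext | None = None,
    standard_id: str | None = None,
    standard_every: int = 8,
    drift_total: float = 0.0,
) -> tuple[list[ScreenSegment], dict]:
    """Simulate a tiled-segment screen with optional planted enhanced sites.

    Segments are labelled ``P1..`` (first genome) and ``F1..`` (second
    genome), positioned on a ``segment_step`` grid.  Every segment binds at
    ``cfg.screen_conc`` according to ``baseline``, except ids listed in
    ``enhanced`` which use their own (stronger) Kd.  Gaussian noise is
    applied to the replicate responses.  If ``standard_id`` is given, a
    standard segment is inserted every ``standard_every`` cycles;
    ``drift_total`` applies a linear multiplicative drift of that total
    fractional size across the run (affecting all responses), for exercising
    :func:`latticebind.spr.drift_correct`.

    Returns ``(segments, truth)`` where truth records the enhanced ids and
    generating models.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    enhanced = dict(enhanced or {})
    if ctx is None:
        # 30-bp duplex: ~650 g/mol per bp
        ctx = MassContext(M_protein=7900.0, M_DNA=19500.0, N=cfg.segment_window, R_L=cfg.r_l_ru)
    rng = _rng(cfg, _STREAM_REDCAT)

    half = (n_segments + 1) // 2
    ids, genomes, positions = [], [], []
    for i in range(n_segments):
        if i < half:
            ids.append(f"P{i + 1}")
            genomes.append("genomeA")
            positions.append(-100 + cfg.segment_step * i)
        else:
            ids.append(f"F{i - half + 1}")
            genomes.append("genomeB")
            positions.append(-100 + cfg.segment_step * (i - half))
    unknown = set(enhanced) - set(ids)
    if unknown:
        raise ValueError(f"enhanced ids not among generated segment ids: {sorted(unknown)}")

    def response_for(kd: float) -> float:
        m = LatticeModel(Ka=1.0 / kd, n=baseline.n, N=baseline.N)
        return density_to_response(solve_binding_density(cfg.screen_conc, m), ctx)

    r_baseline = response_for(baseline.Kd)
    segments: list[ScreenSegment] = []
    cycle = 0
    total_cycles_est = n_segments + (n_segments // max(standard_every, 1) + 2 if standard_id else 0)

    def drift(cyc: int) -> float:
        if drift_total == 0.0 or total_cycles_est <= 1:
            return 1.0
        return 1.0 + drift_total * cyc / (total_cycles_est - 1)

    def make_segment(seg_id: str, genome: str, position: int, r_true: float, cyc: int) -> ScreenSegment:
        noise = cfg.spr_additive_sd_ru * rng.standard_normal(cfg.replicates)
        mult = 1.0 + cfg.spr_multiplicative_cv * rng.standard_normal(cfg.replicates)
        responses = (r_true * drift(cyc) * mult + noise).tolist()
        return ScreenSegment(
            segment_id=seg_id, genome=genome, position=position, R_L=ctx.R_L,
            responses=responses, cycle=cyc,
        )

    for seg_id, genome, pos in zip(ids, genomes, positions):
        if standard_id and cycle % (standard_every + 1) == 0:
            segments.append(make_segment(standard_id, "standard", 0, r_baseline, cycle))
            cycle += 1
        kd = enhanced.get(seg_id, baseline.Kd)
        segments.append(make_segment(seg_id, genome, pos, response_for(kd), cycle))
        cycle += 1
    if standard_id:
        segments.append(make_segment(standard_id, "standard", 0, r_baseline, cycle))

    truth = {
        "baseline_Kd": baseline.Kd,
        "enhanced": enhanced,
        "screen_conc": cfg.screen_conc,
        "ctx": ctx,
        "n": baseline.n,
        "N": baseline.N,
    }
    return segments, truth


def gen_auc_species(
    stoichiometries: list[int],
    M_DNA: float,
    M_protein: float,
    f_f0: float = 1.5,
    vbar_DNA: float = VBAR_DNA,
    vbar_protein: float = VBAR_PROTEIN_DEFAULT,
    buffer: BufferConditions = WATER_20C,
    cfg: SimConfig = SimConfig(),
) -> pd.DataFrame:
    """Simulate sedimentation coefficients for planted bound states.

    For each k in ``stoichiometries`` the complex mass ``M_DNA + k*M_protein``
    and its mass-weighted vbar give the noise-free s20,w through the inverse
    Svedberg relation; multiplicative Gaussian noise of CV ``cfg.auc_s_cv``
    is then applied.  Returns a DataFrame with the observed ``s20w_S``,
    ``f_f0``, per-species ids and the planted ``k_true``.
    """
    rng = _rng(cfg, _STREAM_AUC)
    rows = []
    for k in stoichiometries:
        if k < 0:
            raise ValueError("stoichiometries must be >= 0")
        mass = M_DNA + k * M_protein
        comps = [(M_DNA, vbar_DNA)] + [(M_protein, vbar_protein)] * k
        vb = weighted_vbar(comps)
        s_true = sedimentation_from_mass(mass, f_f0, vb, buffer)
        s_obs = s_true * (1.0 + cfg.auc_s_cv * rng.standard_normal())
        rows.append(
            {
                "species_id": f"k{k}",
                "s20w_S": s_obs,
                "f_f0": f_f0,
                "M_DNA": M_DNA,
                "M_protein": M_protein,
                "k_true": k,
                "s_true_S": s_true,
            }
        )
    return pd.DataFrame(rows)


_AA_POOL = "ACDEFGHIKLMNQRSTVWY"  # proline handled separately


def fraction_bound(ratio: float, protein_conc: float, Kd: float) -> float:
    """Bound fraction of protein for 1:1 binding at a given ligand/protein ratio.

    Exact quadratic solution with ligand depletion: total ligand
    ``D = ratio * protein_conc``.
    """
    if ratio < 0:
        raise ValueError("molar ratio must be >= 0")
    if ratio == 0:
        return 0.0
    p, d = protein_conc, ratio * protein_conc
    b = p + d + Kd
    complex_conc = (b - math.sqrt(b * b - 4 * p * d)) / 2.0
    return complex_conc / p


def gen_csp(
    surface_residues: set[int],
    delta_max: float = 0.3,
    Kd: float = 1.0e-3,
    ratios: list[float] | None = None,
    cfg: SimConfig = SimConfig(),
    n_residues: int = 68,
    proline_positions: set[int] = frozenset({12, 41}),
) -> tuple[pd.DataFrame, dict]:
    """Simulate a fast-exchange HSQC titration over a planted binding surface.

    Residues 1..n_residues get random but seed-stable free-state peak
    positions and types (prolines at ``proline_positions`` are never
    observed).  Surface residues carry maximal shift changes of magnitude
    ~``delta_max`` ppm (1H, with matching 15N changes scaled by 1/alpha);
    background residues move only by noise.  At each DNA/protein molar
    ratio the observed peak is ``free + fraction_bound * delta_max_vec`` plus
    Gaussian scatter of SD ``cfg.csp_background_sd_ppm``.

    ``ratios`` must be sorted ascending and include the free state (0);
    default ``[0, 0.2, 1.2, 4.8, 19.2]``.  Returns the long-format peak
    table (columns ratio, residue_id, residue_type, H_ppm, N_ppm) and the
    truth dict.
    """
    if ratios is None:
        ratios = [0.0, 0.2, 1.2, 4.8, 19.2]
    if sorted(ratios) != list(ratios):
        raise ValueError("ratios must be sorted ascending")
    if ratios[0] != 0 or len(ratios) < 2:
        raise ValueError("ratios must include the free state (0) and at least one titration point")
    bad = {r for r in surface_residues if not 1 <= r <= n_residues}
    if bad:
        raise ValueError(f"surface residues outside 1..{n_residues}: {sorted(bad)}")
    rng = _rng(cfg, _STREAM_CSP)

    types = {}
    for rid in range(1, n_residues + 1):
        types[rid] = "P" if rid in proline_positions else _AA_POOL[rng.integers(len(_AA_POOL))]
    h_free = 6.5 + 3.5 * rng.random(n_residues)  # ppm, amide region
    n_free = 105.0 + 25.0 * rng.random(n_residues)

    # per-residue maximal changes; 15N scaled so both terms contribute
    ddh_max = np.zeros(n_residues)
    ddn_max = np.zeros(n_residues)
    for rid in surface_residues:
        sign_h, sign_n = rng.choice([-1.0, 1.0], size=2)
        ddh_max[rid - 1] = sign_h * delta_max * rng.uniform(0.5, 1.0)
        ddn_max[rid - 1] = sign_n * (delta_max / 0.14) * rng.uniform(0.5, 1.0)

    rows = []
    for ratio in ratios:
        fb = fraction_bound(ratio, cfg.protein_conc, Kd)
        for rid in range(1, n_residues + 1):
            if types[rid] == "P":
                continue  # no backbone amide peak
            noise_h, noise_n = cfg.csp_background_sd_ppm * rng.standard_normal(2)
            rows.append(
                {
                    "ratio": ratio,
                    "residue_id": rid,
                    "residue_type": types[rid],
                    "H_ppm": h_free[rid - 1] + fb * ddh_max[rid - 1] + noise_h,
                    "N_ppm": n_free[rid - 1] + fb * ddn_max[rid - 1] + noise_n,
                }
            )
    table = pd.DataFrame(rows)
    truth = {
        "surface": set(surface_residues),
        "delta_max": delta_max,
        "Kd": Kd,
        "fraction_bound_final": fraction_bound(ratios[-1], cfg.protein_conc, Kd),
        "types": types,
    }
    return table, truth
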