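"""CSV/FASTA readers and writers, sequence tiling, run manifests.

All tables are plain comma-separated UTF-8 with a mandatory header row and
'.' decimal separator; column names carry their units (``concentration_M``,
``R_eq_RU``, ``s20w_S``...).  Genome coordinates are 0-based; screen-segment
offsets are signed relative to the first base of the small-terminase start
codon.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

__all__ = [
    "tile_sequence",
    "read_table",
    "write_table",
    "read_fasta",
    "RunManifest",
    "SPR_FIT_SCHEMA",
    "REDCAT_SCHEMA",
    "AUC_SCHEMA",
    "CSP_SCHEMA",
]

_DNA = re.compile(r"[ACGT]*\Z")

# mandatory column -> dtype ("float", "int", "str", "bool")
SPR_FIT_SCHEMA = {
    "concentration_M": "float",
    "R_eq_RU": "float",
    "R_L_RU": "float",
    "replicate": "str",
    "M_protein": "float",
    "M_DNA": "float",
    "N_bp": "int",
}
REDCAT_SCHEMA = {
    "segment_id": "str",
    "genome": "str",
    "position": "int",
    "concentration_M": "float",
    "R_eq_RU": "float",
    "R_L_RU": "float",
    "replicate": "str",
    "M_protein": "float",
    "M_DNA": "float",
    "N_bp": "int",
}
AUC_SCHEMA = {
    "species_id": "str",
    "s20w_S": "float",
    "f_f0": "float",
    "M_DNA": "float",
    "M_protein": "float",
    "N_bp": "int",
    "saturated": "bool",
}
CSP_SCHEMA = {
    "residue_id": "int",
    "residue_type": "str",
    "H_free_ppm": "float",
    "N_free_ppm": "float",
    "H_bound_ppm": "float",
    "N_bound_ppm": "float",
}


def tile_sequence(sequence: str, window: int = 30, overlap: int = 5) -> list[tuple[int, str]]:
    """Tile a DNA sequence into overlapping windows.

    Windows start every ``window - overlap`` bp (0-based positions).  If the
    final step would overshoot, a last window is anchored to the sequence
    end so every base is covered.  The sequence must be over {A, C, G, T}
    (case-insensitive).
    """
    if not window > overlap >= 0:
        raise ValueError(f"require window > overlap >= 0, got window={window}, overlap={overlap}")
    seq = sequence.upper()
    m = _DNA.match(seq)
    if m is None or m.end() != len(seq):
        bad = next(i for i, c in enumerate(seq) if c not in "ACGT")
        raise ValueError(f"non-ACGT character {sequence[bad]!r} at offset {bad}")
    if len(seq) < window:
        raise ValueError(f"sequence length {len(seq)} shorter than window {window}")
    step = window - overlap
    positions = list(range(0, len(seq) - window + 1, step))
    last = len(seq) - window
    if positions[-1] != last:
        positions.append(last)
    return [(p, seq[p : p + window]) for p in positions]


_CONVERTERS = {
    "float": float,
    "int": int,
    "str": str,
    "bool": lambda x: str(x).strip().lower() in {"1", "true", "yes"},
}


def read_table(path: str | Path, schema: dict[str, str]) -> pd.DataFrame:
    """Read and validate a CSV table against a mandatory-column schema.

    Extra columns are tolerated (and logged via the returned frame's attrs);
    missing mandatory columns raise with the full expected schema; a
    malformed cell raises with its row and column coordinates (1-based data
    rows, as in the file minus the header).
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in schema if c not in raw.columns]
    if missing:
        raise ValueError(
            f"{path}: missing mandatory column(s) {missing}; expected schema: "
            + ", ".join(f"{c} ({t})" for c, t in schema.items())
        )
    extra = [c for c in raw.columns if c not in schema]
    out = {}
    for col, typ in schema.items():
        conv = _CONVERTERS[typ]
        vals = []
        for i, cell in enumerate(raw[col]):
            try:
                vals.append(conv(cell))
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path}: malformed {typ} value {cell!r} at data row {i + 1}, column {col!r}"
                ) from exc
        out[col] = vals
    frame = pd.DataFrame(out)
    for c in extra:
        frame[c] = raw[c]
    frame.attrs["extra_columns"] = extra
    return frame


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a table as plain CSV (UTF-8, header, no index)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_fasta(path: str | Path) -> str:
    """Read a single-record FASTA file and return its sequence."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected a single FASTA record, found {len(records)}")
    return str(records[0].seq)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written alongside every analysis run's outputs."""

    command: str
    parameters: dict
    input_digests: dict[str, str] = field(default_factory=dict)
    version: str = ""
    timestamp: str = ""

    @classmethod
    def create(cls, command: str, parameters: dict, inputs: list[str | Path] = ()) -> "RunManifest":
        from . import __version__

        return cls(
            command=command,
            parameters={k: v for k, v in parameters.items()},
            input_digests={str(p): _sha256(Path(p)) for p in inputs},
            version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(),
        )

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "run_manifest.json"
        path.write_text(json.dumps(self.__dict__, indent=2, default=str) + "\n")
        return path
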