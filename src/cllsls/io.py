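"""Read and write annotated rearrangements (AIRR rearrangement TSV).

The package consumes rearrangements that have already been annotated
upstream (gene calls, amino-acid junction, germline V identity); no raw-read
processing or germline alignment happens here. CDR3s are derived from the
IMGT junction by removing the conserved anchor residues (C104 and W118/F118).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from cllsls.catalog import strip_allele

logger = logging.getLogger(__name__)

_REQUIRED_AIRR = ["sequence_id", "v_call", "j_call", "junction_aa", "productive"]
_TRUE_STRINGS = {"t", "true", "1", "yes", "y"}


@dataclass(frozen=True)
class Rearrangement:
    """One annotated V(D)J rearrangement (heavy or light chain)."""

    sequence_id: str
    v_call: str
    j_call: str
    junction_aa: str
    d_call: str = ""
    v_identity: float | None = None
    sample_id: str = ""
    population: str = ""
    isotype: str = ""
    productive: bool = True

    @property
    def cdr3_aa(self) -> str:
        """IMGT CDR3: the junction minus the anchor C and W/F."""
        return self.junction_aa[1:-1]

    @property
    def chain(self) -> str:
        """H, K or L, derived from the V gene locus prefix."""
        v = self.v_call.upper()
        if v.startswith("IGH"):
            return "H"
        if v.startswith("IGK"):
            return "K"
        if v.startswith("IGL"):
            return "L"
        raise ValueError(f"cannot derive chain from v_call {self.v_call!r}")


@dataclass(frozen=True)
class PairedCell:
    """A single cell's productive heavy and light rearrangements."""

    cell_id: str
    heavy: Rearrangement
    light: Rearrangement
    population: str = ""

    def __post_init__(self) -> None:
        if self.heavy.chain != "H":
            raise ValueError(f"cell {self.cell_id}: heavy contig is not an IGH rearrangement")
        if self.light.chain not in ("K", "L"):
            raise ValueError(f"cell {self.cell_id}: light contig is not IGK/IGL")


def _as_bool(value) -> bool:
    return str(value).strip().lower() in _TRUE_STRINGS


def _normalize_identity(value) -> float | None:
    """Accept germline V identity as a fraction or a percentage."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip().rstrip("%")
    if not s:
        return None
    x = float(s)
    if x > 1.0:
        x /= 100.0
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"v_identity out of range: {value!r}")
    return x


def read_airr(
    path: str | Path,
    sample_col: str = "sample_id",
    population_col: str = "population",
) -> list[Rearrangement]:
    """Load an AIRR rearrangement TSV, keeping productive, junction-bearing rows.

    Non-productive rows and rows whose junction is missing, too short, or
    contains a stop codon are dropped with a logged count. Gzip input is
    handled transparently by the reader.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_AIRR if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required AIRR column(s) {missing}")
    if df.empty:
        logger.warning("%s: empty rearrangement file", path)
        return []

    out: list[Rearrangement] = []
    n_nonproductive = n_bad_junction = 0
    for row in df.itertuples(index=False):
        if not _as_bool(getattr(row, "productive")):
            n_nonproductive += 1
            continue
        junction = str(row.junction_aa).strip()
        if len(junction) < 3 or "*" in junction:
            n_bad_junction += 1
            continue
        out.append(
            Rearrangement(
                sequence_id=str(row.sequence_id),
                v_call=str(row.v_call).strip(),
                j_call=str(row.j_call).strip(),
                junction_aa=junction,
                d_call=str(getattr(row, "d_call", "")).strip(),
                v_identity=_normalize_identity(getattr(row, "v_identity", None)),
                sample_id=str(getattr(row, sample_col, "")).strip(),
                population=str(getattr(row, population_col, "")).strip(),
                isotype=str(getattr(row, "isotype", "")).strip(),
                productive=True,
            )
        )
    if n_nonproductive or n_bad_junction:
        logger.info(
            "%s: dropped %d non-productive and %d stop-codon/short-junction rows",
            path,
            n_nonproductive,
            n_bad_junction,
        )
    return out


def write_airr(rearrangements: list[Rearrangement], path: str | Path) -> None:
    """Write rearrangements as an AIRR rearrangement TSV."""
    rows = [
        {
            "sequence_id": r.sequence_id,
            "v_call": r.v_call,
            "d_call": r.d_call,
            "j_call": r.j_call,
            "junction_aa": r.junction_aa,
            "v_identity": "" if r.v_identity is None else f"{r.v_identity:.6f}",
            "productive": "T" if r.productive else "F",
            "sample_id": r.sample_id,
            "population": r.population,
            "isotype": r.isotype,
        }
        for r in rearrangements
    ]
    cols = [
        "sequence_id",
        "v_call",
        "d_call",
        "j_call",
        "junction_aa",
        "v_identity",
        "productive",
        "sample_id",
        "population",
        "isotype",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def unique_key(r: Rearrangement, level: str = "aa") -> str:
    """Clonotype key used to collapse duplicate rearrangements before counting.

    Default key: allele-stripped V gene, allele-stripped J gene and the
    amino-acid junction. ``level="aa"`` is the only collapsing level the
    key itself distinguishes; nucleotide-level collapsing amounts to
    using distinct junction strings upstream.
    """
    return f"{strip_allele(r.v_call)}|{strip_allele(r.j_call)}|{r.junction_aa}"


def collapse_unique(rearrangements: list[Rearrangement]) -> dict[str, Rearrangement]:
    """Collapse rearrangements by :func:`unique_key`.

    The representative keeps the first occurrence's annotations, with
    v_identity replaced by the mean over duplicates that report one.
    Idempotent: collapsing an already-collapsed list is a no-op.
    """
    reps: dict[str, Rearrangement] = {}
    identities: dict[str, list[float]] = {}
    for r in rearrangements:
        key = unique_key(r)
        if key not in reps:
            reps[key] = r
            identities[key] = []
        if r.v_identity is not None:
            identities[key].append(r.v_identity)
    for key, vals in identities.items():
        if vals:
            mean = sum(vals) / len(vals)
            if reps[key].v_identity != mean:
                reps[key] = replace(reps[key], v_identity=mean)
    return reps


# Column aliases for 10x "filtered_contig_annotations"-style tables.
_PAIRED_ALIASES = {
    "cell_id": ("cell_id", "barcode"),
    "v_call": ("v_call", "v_gene"),
    "d_call": ("d_call", "d_gene"),
    "j_call": ("j_call", "j_gene"),
    "junction_aa": ("junction_aa", "cdr3"),
    "productive": ("productive",),
    "sample_id": ("sample_id", "origin"),
    "population": ("population",),
}


def _pick(df: pd.DataFrame, field: str) -> str | None:
    for name in _PAIRED_ALIASES[field]:
        if name in df.columns:
            return name
    return None


def read_paired(path: str | Path) -> list[PairedCell]:
    """Load a single-cell contig table and pair heavy with light chains.

    Accepts AIRR-style column names or the 10x ``filtered_contig_annotations``
    layout (barcode/v_gene/cdr3/...). Only cells with exactly one productive
    heavy and exactly one productive light contig are retained; ambiguous or
    incomplete cells are dropped with a logged count.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = {f: _pick(df, f) for f in _PAIRED_ALIASES}
    for required in ("cell_id", "v_call", "j_call", "junction_aa", "productive"):
        if cols[required] is None:
            raise ValueError(f"{path}: no column for {required!r} (aliases {_PAIRED_ALIASES[required]})")

    cells: list[PairedCell] = []
    n_dropped = 0
    for cell_id, group in df.groupby(cols["cell_id"], sort=True):
        heavy: list[Rearrangement] = []
        light: list[Rearrangement] = []
        population = ""
        for row in group.itertuples(index=False):
            get = lambda f, default="": (
                str(getattr(row, cols[f])) if cols[f] else default
            )
            if not _as_bool(get("productive")):
                continue
            junction = get("junction_aa").strip()
            if len(junction) < 3 or "*" in junction:
                continue
            r = Rearrangement(
                sequence_id=str(cell_id),
                v_call=get("v_call").strip(),
                j_call=get("j_call").strip(),
                junction_aa=junction,
                d_call=get("d_call").strip(),
                sample_id=get("sample_id").strip(),
                population=get("population").strip(),
            )
            population = r.population or population
            try:
                chain = r.chain
            except ValueError:
                continue
            (heavy if chain == "H" else light).append(r)
        if len(heavy) == 1 and len(light) == 1:
            cells.append(
                PairedCell(cell_id=str(cell_id), heavy=heavy[0], light=light[0], population=population)
            )
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("%s: dropped %d cells without exactly 1 heavy + 1 light contig", path, n_dropped)
    return cells
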