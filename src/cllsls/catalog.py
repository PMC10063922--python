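"""Stereotyped-subset reference catalog and the IGHV phylogenetic clan map.

A stereotyped CLL subset is defined by the IGHV genes its members use, the
phylogenetic clan those genes belong to, a fixed VH CDR3 length, a consensus
CDR3 amino-acid sequence, a subset-specific CDR3 motif with a fixed offset,
a canonical IGHV-mutation class (U = unmutated, M = mutated) and, for some
subsets, a near-obligate light-chain V gene.

Coordinate convention used throughout the package: the CDR3 is the IMGT
junction minus the conserved anchor C104 and W118/F118, and ``motif_offset``
is the 0-based index of the motif's first residue within that CDR3.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AA_ALPHABET)
_MOTIF_SET = _AA_SET | {"X"}

#: Standard immunogenetic clan convention for the seven human IGHV families.
DEFAULT_FAMILY_CLANS = {
    "IGHV1": "I",
    "IGHV5": "I",
    "IGHV7": "I",
    "IGHV2": "II",
    "IGHV4": "II",
    "IGHV6": "II",
    "IGHV3": "III",
}

_GENE_RE = re.compile(r"^(IGHV[1-7])(?:[-/S].*)?$")


def strip_allele(gene: str) -> str:
    """Drop the IMGT allele suffix: ``IGHV1-69*01`` -> ``IGHV1-69``."""
    return gene.split("*", 1)[0].strip()


def gene_family(v_gene: str) -> str:
    """IGHV family of a heavy-chain V gene name; raises on non-IGHV genes."""
    name = strip_allele(v_gene)
    m = _GENE_RE.match(name)
    if m is None:
        raise ValueError(f"not a recognisable IGHV gene name: {v_gene!r}")
    return m.group(1)


@dataclass(frozen=True)
class ClanMap:
    """Mapping of IGHV gene families to phylogenetic clans I/II/III.

    ``associations`` lists clan pairs considered "phylogenetically
    associated" for satellite matching; the default (empty) means each clan
    is associated only with itself, i.e. same-clan association.
    """

    family_to_clan: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_CLANS)
    )
    associations: frozenset[frozenset[str]] = frozenset()

    def __post_init__(self) -> None:
        missing = set(DEFAULT_FAMILY_CLANS) - set(self.family_to_clan)
        if missing:
            raise ValueError(f"clan map must cover all IGHV families; missing {sorted(missing)}")

    def clan_of(self, v_gene: str) -> str:
        return self.family_to_clan[gene_family(v_gene)]

    def associated(self, clan_a: str, clan_b: str) -> bool:
        """Whether two clans count as phylogenetically associated."""
        if clan_a == clan_b:
            return True
        return frozenset((clan_a, clan_b)) in self.associations


DEFAULT_CLAN_MAP = ClanMap()


def clan_of(v_gene: str, clans: ClanMap | None = None) -> str:
    """Clan label (I/II/III) of an IGHV gene; allele suffixes are ignored."""
    return (clans or DEFAULT_CLAN_MAP).clan_of(v_gene)


@dataclass(frozen=True)
class SubsetDefinition:
    """One stereotyped subset's reference entry."""

    subset_id: str
    ighv_genes: frozenset[str]
    cdr3_length: int
    consensus_cdr3: str
    motif: str
    motif_offset: int
    mutation_class: str
    light_chain_gene: str | None = None
    clan: str = ""

    def __post_init__(self) -> None:
        if not self.subset_id:
            raise ValueError("subset_id must be non-empty")
        if not self.ighv_genes:
            raise ValueError(f"subset {self.subset_id}: at least one IGHV gene required")
        clans = {clan_of(g) for g in self.ighv_genes}
        if len(clans) != 1:
            raise ValueError(
                f"subset {self.subset_id}: IGHV genes span clans {sorted(clans)}; "
                "a subset's genes must share one clan"
            )
        derived = clans.pop()
        if self.clan and self.clan != derived:
            raise ValueError(
                f"subset {self.subset_id}: declared clan {self.clan} does not match "
                f"gene-derived clan {derived}"
            )
        object.__setattr__(self, "clan", derived)
        if len(self.consensus_cdr3) != self.cdr3_length:
            raise ValueError(
                f"subset {self.subset_id}: consensus CDR3 length "
                f"{len(self.consensus_cdr3)} != cdr3_length {self.cdr3_length}"
            )
        bad = set(self.consensus_cdr3) - _AA_SET
        if bad:
            raise ValueError(f"subset {self.subset_id}: consensus has non-residue {sorted(bad)}")
        if not self.motif:
            raise ValueError(f"subset {self.subset_id}: motif must be non-empty")
        bad = set(self.motif) - _MOTIF_SET
        if bad:
            raise ValueError(f"subset {self.subset_id}: motif has invalid symbol {sorted(bad)}")
        if self.motif_offset < 0:
            raise ValueError(f"subset {self.subset_id}: motif_offset must be >= 0")
        if self.motif_offset + len(self.motif) > self.cdr3_length:
            raise ValueError(
                f"subset {self.subset_id}: motif (offset {self.motif_offset}, "
                f"length {len(self.motif)}) overruns CDR3 of length {self.cdr3_length}"
            )
        if self.mutation_class not in ("U", "M"):
            raise ValueError(
                f"subset {self.subset_id}: mutation_class must be U or M, "
                f"got {self.mutation_class!r}"
            )


_CATALOG_COLUMNS = [
    "subset_id",
    "ighv_genes",
    "cdr3_length",
    "consensus_cdr3",
    "motif",
    "motif_offset",
    "mutation_class",
    "light_chain_gene",
]


def load_catalog(path: str | Path) -> list[SubsetDefinition]:
    """Read a subset catalog TSV and validate every row.

    Columns: subset_id, ighv_genes (comma-separated), cdr3_length,
    consensus_cdr3, motif, motif_offset, mutation_class, light_chain_gene
    (may be empty). Extra columns are ignored.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"catalog {path}: missing columns {missing}")
    defs: list[SubsetDefinition] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            sid = row.subset_id.strip()
            if sid in seen:
                raise ValueError(f"duplicate subset_id {sid!r}")
            seen.add(sid)
            genes = frozenset(g.strip() for g in row.ighv_genes.split(",") if g.strip())
            light = row.light_chain_gene.strip() or None
            defs.append(
                SubsetDefinition(
                    subset_id=sid,
                    ighv_genes=genes,
                    cdr3_length=int(row.cdr3_length),
                    consensus_cdr3=row.consensus_cdr3.strip(),
                    motif=row.motif.strip(),
                    motif_offset=int(row.motif_offset),
                    mutation_class=row.mutation_class.strip(),
                    light_chain_gene=light,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"catalog {path}, row {i}: {exc}") from exc
    return defs


def write_catalog(subsets: list[SubsetDefinition], path: str | Path) -> None:
    """Write subset definitions back out in the catalog TSV schema."""
    rows = [
        {
            "subset_id": s.subset_id,
            "ighv_genes": ",".join(sorted(s.ighv_genes)),
            "cdr3_length": s.cdr3_length,
            "consensus_cdr3": s.consensus_cdr3,
            "motif": s.motif,
            "motif_offset": s.motif_offset,
            "mutation_class": s.mutation_class,
            "light_chain_gene": s.light_chain_gene or "",
        }
        for s in subsets
    ]
    pd.DataFrame(rows, columns=_CATALOG_COLUMNS).to_csv(path, sep="\t", index=False)


def toy_catalog_path() -> Path:
    """Path to the packaged four-subset toy catalog used in tests/examples."""
    return Path(str(resources.files("cllsls").joinpath("data/toy_catalog.tsv")))


def starter_catalog_path() -> Path:
    """Path to the starter catalog of named CLL subsets.

    Genes, mutation classes and light-chain restrictions follow the
    literature where stated; consensus CDR3s and motifs are SYNTHETIC
    placeholders (the published definitions are not redistributed here) and
    are flagged per row in the ``provenance`` column. Replace with a real
    subset catalog for any analysis of actual repertoires.
    """
    return Path(str(resources.files("cllsls").joinpath("data/starter_catalog_synthetic.tsv")))
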