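"""Standard and satellite CLL stereotype assignment.

A heavy-chain rearrangement is assigned to a stereotyped subset as a
*standard* match when all four clustering criteria hold:

  (i)   its IGHV gene belongs to the subset's phylogenetic clan,
  (ii)  its VH CDR3 has >= 50% amino-acid identity and >= 70% similarity to
        the subset's consensus CDR3,
  (iii) its VH CDR3 length equals the subset's CDR3 length, and
  (iv)  the subset-specific motif occurs at the identical CDR3 offset.

A *satellite* match relaxes this to: phylogenetically associated IGHV
genes, a CDR3 length difference of at most 2 amino acids, and the motif
present at an offset within +/- 2 of the subset's offset. The satellite
tier deliberately applies no identity/similarity thresholds (the values are
still recorded). A sequence with a standard match is never also counted as
a satellite: the two tiers are disjoint.

Similarity counts a position as matching when the two residues are
identical or fall in the same conservative-substitution group; identity is
therefore never above similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from cllsls.catalog import ClanMap, DEFAULT_CLAN_MAP, SubsetDefinition
from cllsls.io import Rearrangement, collapse_unique

logger = logging.getLogger(__name__)

#: Conservative amino-acid substitution classes used for CDR3 similarity:
#: small/aliphatic, aromatic, sulfur-bearing, hydroxyl, basic, acidic/amide,
#: and proline on its own.
DEFAULT_SIMILARITY_GROUPS: tuple[frozenset[str], ...] = (
    frozenset("GAVLI"),
    frozenset("FYW"),
    frozenset("CM"),
    frozenset("ST"),
    frozenset("KRH"),
    frozenset("DENQ"),
    frozenset("P"),
)


def _group_index(groups) -> dict[str, int]:
    idx: dict[str, int] = {}
    for i, g in enumerate(groups):
        for aa in g:
            if aa in idx:
                raise ValueError(f"residue {aa!r} appears in more than one similarity group")
            idx[aa] = i
    return idx


_DEFAULT_GROUP_INDEX = _group_index(DEFAULT_SIMILARITY_GROUPS)


def aa_identity(a: str, b: str) -> float:
    """Fraction of aligned positions with identical residues."""
    if len(a) != len(b) or not a:
        raise ValueError(f"sequences must have equal non-zero length, got {len(a)} and {len(b)}")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def aa_similarity(a: str, b: str, groups=None) -> float:
    """Fraction of positions identical or in the same substitution group."""
    if len(a) != len(b) or not a:
        raise ValueError(f"sequences must have equal non-zero length, got {len(a)} and {len(b)}")
    idx = _DEFAULT_GROUP_INDEX if groups is None else _group_index(groups)
    n = 0
    for x, y in zip(a, b):
        if x == y:
            n += 1
        else:
            try:
                n += idx[x] == idx[y]
            except KeyError as exc:
                raise ValueError(f"residue outside similarity alphabet: {exc}") from exc
    return n / len(a)


def find_motif(cdr3: str, motif: str) -> list[int]:
    """All 0-based offsets where the motif matches; ``X`` matches any residue."""
    if not motif:
        raise ValueError("motif must be non-empty")
    m = len(motif)
    if "X" not in motif:
        # fast path: plain substring scan
        hits, start = [], cdr3.find(motif)
        while start != -1:
            hits.append(start)
            start = cdr3.find(motif, start + 1)
        return hits
    hits = []
    for o in range(len(cdr3) - m + 1):
        if all(p == "X" or p == c for p, c in zip(motif, cdr3[o : o + m])):
            hits.append(o)
    return hits


@dataclass(frozen=True)
class Assignment:
    """Result of matching one unique rearrangement against the catalog."""

    sequence_key: str
    subset_id: str
    match_type: str  # standard | satellite | none
    identity: float = 0.0
    similarity: float = 0.0
    length_delta: int = 0
    offset_delta: int = 0
    shm_class: str = "unknown"  # U | M | unknown
    concordant_shm: bool | None = None
    v_call: str = ""
    sample_populations: tuple = field(default=(), compare=False)


def _anchored_scores(cdr3: str, consensus: str, offset_delta: int, groups) -> tuple[float, float]:
    """Identity/similarity with the two CDR3s aligned on the matched motif.

    cdr3 position i is compared to consensus position i - offset_delta over
    the overlapping range; used for satellite matches where lengths and
    offsets may differ. Reduces to the plain positionwise comparison when
    lengths are equal and offset_delta is 0.
    """
    lo = max(0, offset_delta)
    hi = min(len(cdr3), len(consensus) + offset_delta)
    if hi <= lo:
        return 0.0, 0.0
    a = cdr3[lo:hi]
    b = consensus[lo - offset_delta : hi - offset_delta]
    return aa_identity(a, b), aa_similarity(a, b, groups)


def match_standard(
    r: Rearrangement,
    s: SubsetDefinition,
    clans: ClanMap | None = None,
    groups=None,
    min_identity: float = 0.5,
    min_similarity: float = 0.7,
) -> Assignment | None:
    """Standard-tier match of one rearrangement against one subset, or None."""
    clans = clans or DEFAULT_CLAN_MAP
    if r.chain != "H":
        raise ValueError(f"{r.sequence_id}: standard matching requires a heavy chain")
    cdr3 = r.cdr3_aa
    if len(cdr3) != s.cdr3_length:
        return None
    if clans.clan_of(r.v_call) != s.clan:
        return None
    if s.motif_offset not in find_motif(cdr3, s.motif):
        return None
    ident = aa_identity(cdr3, s.consensus_cdr3)
    simil = aa_similarity(cdr3, s.consensus_cdr3, groups)
    if ident < min_identity or simil < min_similarity:
        return None
    from cllsls.io import unique_key

    return Assignment(
        sequence_key=unique_key(r),
        subset_id=s.subset_id,
        match_type="standard",
        identity=ident,
        similarity=simil,
        length_delta=0,
        offset_delta=0,
        v_call=r.v_call,
    )


def match_satellite(
    r: Rearrangement,
    s: SubsetDefinition,
    clans: ClanMap | None = None,
    groups=None,
    max_length_delta: int = 2,
    max_offset_delta: int = 2,
) -> Assignment | None:
    """Satellite-tier match: relaxed length/offset, no identity thresholds."""
    clans = clans or DEFAULT_CLAN_MAP
    if r.chain != "H":
        raise ValueError(f"{r.sequence_id}: satellite matching requires a heavy chain")
    cdr3 = r.cdr3_aa
    length_delta = len(cdr3) - s.cdr3_length
    if abs(length_delta) > max_length_delta:
        return None
    if not clans.associated(clans.clan_of(r.v_call), s.clan):
        return None
    offsets = [o for o in find_motif(cdr3, s.motif) if abs(o - s.motif_offset) <= max_offset_delta]
    if not offsets:
        return None
    # minimal |delta|; ties resolved toward the more negative delta
    best = min(offsets, key=lambda o: (abs(o - s.motif_offset), o - s.motif_offset))
    offset_delta = best - s.motif_offset
    ident, simil = _anchored_scores(cdr3, s.consensus_cdr3, offset_delta, groups)
    from cllsls.io import unique_key

    return Assignment(
        sequence_key=unique_key(r),
        subset_id=s.subset_id,
        match_type="satellite",
        identity=ident,
        similarity=simil,
        length_delta=length_delta,
        offset_delta=offset_delta,
        v_call=r.v_call,
    )


def _classify(v_identity: float | None, cutoff: float) -> str:
    if v_identity is None:
        return "unknown"
    return "U" if v_identity >= cutoff else "M"


def _best(cands: list[tuple[Assignment, SubsetDefinition]]):
    """Tie-break multi-subset matches: similarity desc, identity desc, id asc."""
    return min(cands, key=lambda c: (-c[0].similarity, -c[0].identity, c[0].subset_id))


def assign_all(
    rearrangements: list[Rearrangement],
    catalog: list[SubsetDefinition],
    clans: ClanMap | None = None,
    groups=None,
    shm_cutoff: float = 0.98,
    min_identity: float = 0.5,
    min_similarity: float = 0.7,
    max_length_delta: int = 2,
    max_offset_delta: int = 2,
) -> list[Assignment]:
    """Assign every unique heavy-chain rearrangement against the catalog.

    Rearrangements are collapsed by clonotype key first. Each key is tried
    at the standard tier against all subsets; only keys without a standard
    match are tried at the satellite tier, so the two tiers are disjoint.
    Multi-subset matches within a tier are resolved by highest similarity,
    then highest identity, then lexicographic subset id (logged). Output is
    sorted by key and thus independent of input order.
    """
    if not catalog:
        raise ValueError("catalog must be non-empty")
    clans = clans or DEFAULT_CLAN_MAP
    reps = collapse_unique([r for r in rearrangements if r.chain == "H"])

    # population labels seen per key, for downstream per-population summaries
    pops: dict[str, set] = {}
    from cllsls.io import unique_key

    for r in rearrangements:
        if r.chain == "H":
            pops.setdefault(unique_key(r), set()).add((r.sample_id, r.population))

    # cheap prefilters: exact length for standard, +/- delta for satellite
    by_length: dict[int, list[SubsetDefinition]] = {}
    for s in catalog:
        by_length.setdefault(s.cdr3_length, []).append(s)

    out: list[Assignment] = []
    n_ties = 0
    for key in sorted(reps):
        r = reps[key]
        cdr3_len = len(r.cdr3_aa)
        shm = _classify(r.v_identity, shm_cutoff)
        sample_pops = tuple(sorted(pops.get(key, ())))

        cands = []
        for s in by_length.get(cdr3_len, ()):
            a = match_standard(r, s, clans, groups, min_identity, min_similarity)
            if a is not None:
                cands.append((a, s))
        if not cands:
            for delta in range(-max_length_delta, max_length_delta + 1):
                for s in by_length.get(cdr3_len - delta, ()):
                    a = match_satellite(r, s, clans, groups, max_length_delta, max_offset_delta)
                    if a is not None:
                        cands.append((a, s))
        if cands:
            if len(cands) > 1:
                n_ties += 1
            a, s = _best(cands)
            out.append(
                Assignment(
                    sequence_key=a.sequence_key,
                    subset_id=a.subset_id,
                    match_type=a.match_type,
                    identity=a.identity,
                    similarity=a.similarity,
                    length_delta=a.length_delta,
                    offset_delta=a.offset_delta,
                    shm_class=shm,
                    concordant_shm=None if shm == "unknown" else shm == s.mutation_class,
                    v_call=r.v_call,
                    sample_populations=sample_pops,
                )
            )
        else:
            out.append(
                Assignment(
                    sequence_key=key,
                    subset_id="",
                    match_type="none",
                    shm_class=shm,
                    v_call=r.v_call,
                    sample_populations=sample_pops,
                )
            )
    if n_ties:
        logger.info("assign_all: %d keys matched multiple subsets; ties broken deterministically", n_ties)
    return out


def write_assignments(assignments: list[Assignment], path) -> None:
    """Write assignments as TSV (one row per unique clonotype key)."""
    import pandas as pd

    rows = [
        {
            "sequence_key": a.sequence_key,
            "subset_id": a.subset_id,
            "match_type": a.match_type,
            "identity": f"{a.identity:.6f}",
            "similarity": f"{a.similarity:.6f}",
            "length_delta": a.length_delta,
            "offset_delta": a.offset_delta,
            "shm_class": a.shm_class,
            "concordant_shm": "" if a.concordant_shm is None else str(a.concordant_shm),
        }
        for a in assignments
    ]
    cols = [
        "sequence_key",
        "subset_id",
        "match_type",
        "identity",
        "similarity",
        "length_delta",
        "offset_delta",
        "shm_class",
        "concordant_shm",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
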