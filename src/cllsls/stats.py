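"""Downstream repertoire quantifications.

Per sample x subpopulation CLL-SLS frequencies (unique clonotypes matched at
the standard or satellite tier over total unique clonotypes), IGHV-mutation
concordance between assigned sequences and each subset's canonical U/M
class, pattern grouping of per-population concordance profiles,
heavy/light-chain pairing restriction checks, and the Kruskal-Wallis test
with Dunn post-hoc comparisons used to compare frequencies across
populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from cllsls.catalog import SubsetDefinition, strip_allele
from cllsls.io import PairedCell, Rearrangement, unique_key
from cllsls.matching import Assignment

logger = logging.getLogger(__name__)


def classify_shm(v_identity: float, cutoff: float = 0.98) -> str:
    """U (unmutated) if germline V identity >= cutoff, else M (mutated).

    The 98% germline-identity threshold is the conventional CLL cutoff.
    """
    if not 0.0 <= v_identity <= 1.0:
        raise ValueError(f"v_identity must be in [0,1], got {v_identity}")
    return "U" if v_identity >= cutoff else "M"


@dataclass
class PopulationSummary:
    """Unique-clonotype counts and CLL-SLS frequencies for one sample x population."""

    sample_id: str
    population: str
    total_unique: int
    n_standard: int
    n_satellite: int
    per_subset_standard: dict[str, int] = field(default_factory=dict)
    per_subset_satellite: dict[str, int] = field(default_factory=dict)

    @property
    def freq_standard(self) -> float:
        return self.n_standard / self.total_unique if self.total_unique else 0.0

    @property
    def freq_satellite(self) -> float:
        return self.n_satellite / self.total_unique if self.total_unique else 0.0


def summarize(
    assignments: list[Assignment],
    rearrangements: list[Rearrangement],
) -> list[PopulationSummary]:
    """Per sample x population totals, tier counts and frequencies.

    Clonotypes are counted once per sample x population group they occur in;
    rows without a population label are grouped under "unlabeled".
    """
    amap = {a.sequence_key: a for a in assignments}
    groups: dict[tuple[str, str], set[str]] = {}
    warned = False
    for r in rearrangements:
        if r.chain != "H":
            continue
        pop = r.population
        if not pop:
            pop = "unlabeled"
            if not warned:
                logger.warning("rearrangements without population label grouped as 'unlabeled'")
                warned = True
        groups.setdefault((r.sample_id, pop), set()).add(unique_key(r))

    out: list[PopulationSummary] = []
    for (sample, pop), keys in sorted(groups.items()):
        std: dict[str, int] = {}
        sat: dict[str, int] = {}
        for key in keys:
            a = amap.get(key)
            if a is None or a.match_type == "none":
                continue
            tier = std if a.match_type == "standard" else sat
            tier[a.subset_id] = tier.get(a.subset_id, 0) + 1
        out.append(
            PopulationSummary(
                sample_id=sample,
                population=pop,
                total_unique=len(keys),
                n_standard=sum(std.values()),
                n_satellite=sum(sat.values()),
                per_subset_standard=std,
                per_subset_satellite=sat,
            )
        )
    return out


def summaries_to_frame(summaries: list[PopulationSummary]) -> pd.DataFrame:
    """Flatten summaries to a tidy frame (one row per sample x population)."""
    return pd.DataFrame(
        {
            "sample_id": s.sample_id,
            "population": s.population,
            "total_unique": s.total_unique,
            "n_standard": s.n_standard,
            "n_satellite": s.n_satellite,
            "freq_standard": s.freq_standard,
            "freq_satellite": s.freq_satellite,
        }
        for s in summaries
    )


@dataclass
class ConcordanceProfile:
    """Per-subset fraction of assigned clonotypes matching the canonical U/M class."""

    subset_id: str
    mutation_class: str
    fractions: dict[str, float] = field(default_factory=dict)  # population -> fraction
    counts: dict[str, int] = field(default_factory=dict)  # population -> n with known SHM
    pattern_id: str | None = None


def concordance_profiles(
    assignments: list[Assignment],
    catalog: list[SubsetDefinition],
    tier: str = "standard",
) -> list[ConcordanceProfile]:
    """Per subset x population SHM concordance fractions.

    Only assignments of the requested tier with known SHM class contribute;
    a clonotype found in several populations contributes to each of them.
    """
    classes = {s.subset_id: s.mutation_class for s in catalog}
    conc: dict[tuple[str, str], list[int]] = {}
    for a in assignments:
        if a.match_type != tier or a.shm_class == "unknown":
            continue
        hit = int(a.shm_class == classes[a.subset_id])
        pops = {pop for _, pop in a.sample_populations} or {"unlabeled"}
        for pop in pops:
            conc.setdefault((a.subset_id, pop), []).append(hit)

    profiles: dict[str, ConcordanceProfile] = {}
    for (sid, pop), hits in sorted(conc.items()):
        p = profiles.setdefault(sid, ConcordanceProfile(subset_id=sid, mutation_class=classes[sid]))
        p.fractions[pop] = float(np.mean(hits))
        p.counts[pop] = len(hits)
    return list(profiles.values())


def group_patterns(profiles: list[ConcordanceProfile], k: int) -> list[ConcordanceProfile]:
    """Group concordance profiles into k patterns.

    Profiles are embedded as per-population concordance vectors (missing
    populations imputed with the profile's own mean) and grouped by
    agglomerative clustering (Euclidean distance, average linkage) cut at k
    clusters. Pattern labels P1..Pk are ordered by first occurrence.
    """
    if k < 1 or k > len(profiles):
        raise ValueError(f"k must be in 1..{len(profiles)}, got {k}")
    pops = sorted({p for prof in profiles for p in prof.fractions})
    mat = np.array(
        [
            [prof.fractions.get(p, float(np.mean(list(prof.fractions.values())))) for p in pops]
            for prof in profiles
        ]
    )
    if len(profiles) == 1:
        labels = np.array([1])
    else:
        link = hierarchy.linkage(mat, method="average", metric="euclidean")
        labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    relabel: dict[int, str] = {}
    for lab in labels:
        if lab not in relabel:
            relabel[lab] = f"P{len(relabel) + 1}"
    return [replace(prof, pattern_id=relabel[lab]) for prof, lab in zip(profiles, labels)]


def light_chain_concordance(
    cells: list[PairedCell],
    assignments: list[Assignment],
    catalog: list[SubsetDefinition],
) -> pd.DataFrame:
    """Check light-chain pairing restriction for assigned cells.

    For each cell whose heavy chain is assigned to a subset: ``concordant``
    if the (allele-stripped) light V gene equals the subset's restriction,
    ``discordant`` if it differs, ``no-restriction`` if the subset declares
    none. Returns per-cell rows; aggregate with groupby as needed.
    """
    amap = {a.sequence_key: a for a in assignments if a.match_type != "none"}
    restriction = {s.subset_id: s.light_chain_gene for s in catalog}
    rows = []
    for cell in cells:
        a = amap.get(unique_key(cell.heavy))
        if a is None:
            continue
        expected = restriction.get(a.subset_id)
        light = strip_allele(cell.light.v_call)
        if expected is None:
            status = "no-restriction"
        elif light == strip_allele(expected):
            status = "concordant"
        else:
            status = "discordant"
        rows.append(
            {
                "cell_id": cell.cell_id,
                "population": cell.population,
                "subset_id": a.subset_id,
                "match_type": a.match_type,
                "light_v": light,
                "expected_light_v": expected or "",
                "status": status,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "population",
            "subset_id",
            "match_type",
            "light_v",
            "expected_light_v",
            "status",
        ],
    )


@dataclass
class KruskalResult:
    statistic: float
    pvalue: float
    posthoc: pd.DataFrame | None = None


def _dunn_posthoc(groups: list[np.ndarray], labels: list[str], p_adjust: str) -> pd.DataFrame:
    """Dunn's rank-sum z tests for all group pairs, with tie correction."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes, idx = [], [], 0
    for g in groups:
        mean_ranks.append(ranks[idx : idx + len(g)].mean())
        sizes.append(len(g))
        idx += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    base_var = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))

    rows = []
    pvals = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append({"group_a": labels[i], "group_b": labels[j], "z": z, "p_raw": p})
            pvals.append(p)
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw"])
    if len(df):
        df["p_adj"] = multipletests(pvals, method=p_adjust)[1]
    else:
        df["p_adj"] = []
    return df


def kruskal_wallis(
    groups: list[list[float]],
    labels: list[str] | None = None,
    posthoc: bool = True,
    p_adjust: str = "holm",
) -> KruskalResult:
    """Kruskal-Wallis H test across groups, with Dunn post-hoc pairs.

    H is tie-corrected with a chi-square p-value; the degenerate case of
    every observation identical yields H = 0, p = 1. Post-hoc pairwise
    comparisons use Dunn's z statistics with Holm adjustment by default.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group must contain at least one observation")
    labels = labels or [f"g{i + 1}" for i in range(len(arrays))]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.kruskal(*arrays)
    ph = _dunn_posthoc(arrays, labels, p_adjust) if posthoc else None
    return KruskalResult(statistic=float(stat), pvalue=float(p), posthoc=ph)
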