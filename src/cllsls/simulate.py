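"""Synthetic AIRR-format repertoires with planted stereotype sequences.

The generator emulates the statistical structure the analysis pipeline
assumes: several donors, each with several B-cell subpopulations; V/D/J
gene usage; junctional diversity that collapses when terminal
deoxynucleotidyl transferase (TdT) is off (neonatal/cord-blood-like
repertoires lack non-templated N additions); per-population somatic
hypermutation (SHM); and stereotype-like sequences planted at controlled
frequencies at either the standard or the satellite tier.

Junctions are generated at the amino-acid level: a CDR3 is composed of a
V-encoded stub, optional N regions, a D-encoded core and a J-encoded tail.
Germline V identity is book-kept from a binomial draw over a nominal
300-nt V segment at the population's SHM rate, consistent in expectation
with the amino-acid substitutions applied.

Every planted sequence receives at least one substitution at a non-motif
CDR3 position so that each plant is a distinct clonotype (as distinct
cells' rearrangements are in real data); each plant is re-verified after
perturbation to still satisfy — and be best-assigned to — its intended
subset and tier, and is resampled otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from cllsls.catalog import AA_ALPHABET, ClanMap, DEFAULT_CLAN_MAP, SubsetDefinition
from cllsls.io import Rearrangement, unique_key
from cllsls.matching import _best, find_motif, match_satellite, match_standard

_V_NT_LENGTH = 300  # nominal V-segment length for germline-identity bookkeeping

DEFAULT_V_USAGE = {
    "IGHV1-69": 0.12,
    "IGHV1-2": 0.08,
    "IGHV5-51": 0.06,
    "IGHV7-4-1": 0.03,
    "IGHV2-5": 0.05,
    "IGHV4-34": 0.10,
    "IGHV4-39": 0.08,
    "IGHV6-1": 0.03,
    "IGHV3-21": 0.10,
    "IGHV3-23": 0.15,
    "IGHV3-48": 0.10,
    "IGHV3-7": 0.10,
}

_V_STUBS = {
    "IGHV1-69": "AR",
    "IGHV1-2": "AR",
    "IGHV5-51": "AH",
    "IGHV7-4-1": "AR",
    "IGHV2-5": "AH",
    "IGHV4-34": "AR",
    "IGHV4-39": "AR",
    "IGHV6-1": "AR",
    "IGHV3-21": "AR",
    "IGHV3-23": "AK",
    "IGHV3-48": "AR",
    "IGHV3-7": "AR",
}

DEFAULT_D_CORES = {
    "IGHD1-26": "SGGS",
    "IGHD2-2": "DIVVV",
    "IGHD3-10": "GSGSY",
    "IGHD3-22": "YDSSG",
    "IGHD6-19": "IAVAG",
}

DEFAULT_J_STUBS = {
    "IGHJ1": "EYFQH",
    "IGHJ2": "YWYFDL",
    "IGHJ3": "AFDI",
    "IGHJ4": "FDY",
    "IGHJ5": "NWFDS",
    "IGHJ6": "YYGMDV",
}


@dataclass(frozen=True)
class PopulationSpec:
    """One B-cell subpopulation: label, size, SHM rate per aa, TdT state."""

    label: str
    n_unique: int
    shm_rate: float = 0.0
    tdt_on: bool = True


@dataclass(frozen=True)
class Planting:
    """Plant one subset at one tier at a per-sequence frequency."""

    subset_id: str
    tier: str  # standard | satellite
    frequency: float
    shm_perturb: float = 0.0

    def __post_init__(self) -> None:
        if self.tier not in ("standard", "satellite"):
            raise ValueError(f"tier must be standard or satellite, got {self.tier!r}")
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError(f"frequency must be in [0,1], got {self.frequency}")
        if not 0.0 <= self.shm_perturb < 1.0:
            raise ValueError(f"shm_perturb must be in [0,1), got {self.shm_perturb}")


@dataclass
class SimConfig:
    """Full simulation configuration; the seed makes runs bit-reproducible."""

    seed: int = 0
    n_samples: int = 3
    populations: list[PopulationSpec] = field(default_factory=list)
    plantings: list[Planting] = field(default_factory=list)
    v_usage: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_V_USAGE))
    mean_n_length: float = 2.5  # mean N-region length per side when TdT is on

    def __post_init__(self) -> None:
        total = sum(p.frequency for p in self.plantings)
        if total > 1.0:
            raise ValueError(f"planted frequencies sum to {total} > 1")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        pops = [PopulationSpec(**p) for p in d.get("populations", [])]
        plants = [Planting(**p) for p in d.get("plantings", [])]
        kwargs = {k: v for k, v in d.items() if k not in ("populations", "plantings")}
        return cls(populations=pops, plantings=plants, **kwargs)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def default_config(seed: int = 0) -> SimConfig:
    """Study-like default conditions for the packaged toy catalog.

    Three donors, a naive-like unmutated population, a memory-like
    population at 6% SHM per aa, and a cord-blood-like TdT-off population.
    Standard plants at a total frequency of 1e-3 and satellite plants at
    1e-2, preserving the ~10:1 satellite:standard excess observed in
    normal repertoires.
    """
    return SimConfig(
        seed=seed,
        n_samples=3,
        populations=[
            PopulationSpec("NAIVE", 12000, shm_rate=0.0, tdt_on=True),
            PopulationSpec("MEM", 12000, shm_rate=0.06, tdt_on=True),
            PopulationSpec("CB", 8000, shm_rate=0.0, tdt_on=False),
        ],
        plantings=[
            Planting("T1", "standard", 0.0005),
            Planting("T2", "standard", 0.0005),
            Planting("T1", "satellite", 0.005),
            Planting("T3", "satellite", 0.005),
        ],
    )


def _rand_aa(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, size=n))


def _substitute(rng: np.random.Generator, residue: str) -> str:
    """A residue drawn uniformly from the 19 alternatives."""
    i = int(rng.integers(0, 19))
    alt = AA_ALPHABET.replace(residue, "")
    return alt[i]


def _apply_shm(rng: np.random.Generator, cdr3: str, rate: float) -> str:
    if rate <= 0:
        return cdr3
    mask = rng.random(len(cdr3)) < rate
    if not mask.any():
        return cdr3
    chars = list(cdr3)
    for i in np.flatnonzero(mask):
        chars[i] = _substitute(rng, chars[i])
    return "".join(chars)


def _v_identity(rng: np.random.Generator, shm_rate: float) -> float:
    if shm_rate <= 0:
        return 1.0
    m = int(rng.binomial(_V_NT_LENGTH, min(shm_rate, 1.0)))
    return 1.0 - m / _V_NT_LENGTH


def _standard_candidates(r: Rearrangement, catalog, clans) -> list:
    cands = []
    for s in catalog:
        if s.cdr3_length == len(r.cdr3_aa):
            a = match_standard(r, s, clans)
            if a is not None:
                cands.append((a, s))
    return cands


def _satellite_candidates(r: Rearrangement, catalog, clans) -> list:
    cands = []
    for s in catalog:
        if abs(len(r.cdr3_aa) - s.cdr3_length) <= 2:
            a = match_satellite(r, s, clans)
            if a is not None:
                cands.append((a, s))
    return cands


class PlantingError(RuntimeError):
    """Raised when a requested plant cannot be constructed within retries."""


def _build_standard_plant(
    rng: np.random.Generator,
    s: SubsetDefinition,
    catalog: list[SubsetDefinition],
    clans: ClanMap,
    shm_perturb: float,
    used_junctions: set[str],
    max_tries: int = 200,
) -> tuple[str, str, str, int]:
    """Consensus-derived CDR3 satisfying — and best-assigned at — the standard tier.

    Returns (cdr3, v_call, j_call, motif_start).
    """
    genes = sorted(s.ighv_genes)
    j_calls = sorted(DEFAULT_J_STUBS)
    span = range(s.motif_offset, s.motif_offset + len(s.motif))
    free = [i for i in range(s.cdr3_length) if i not in span]
    for attempt in range(max_tries):
        chars = list(s.consensus_cdr3)
        mutated = 0
        for i in free:
            if rng.random() < shm_perturb:
                chars[i] = _substitute(rng, chars[i])
                mutated += 1
        # uniquifying junctional variation: at least one substitution, more
        # when the single-substitution neighbourhood is getting crowded
        n_uniq = max(1 + attempt // 10 - mutated, 1 if not mutated else 0)
        if free and n_uniq > 0:
            for i in rng.choice(len(free), size=min(n_uniq, len(free)), replace=False):
                chars[free[i]] = _substitute(rng, chars[free[i]])
        cdr3 = "".join(chars)
        junction = f"C{cdr3}W"
        if junction in used_junctions:
            continue
        v_call = genes[int(rng.integers(0, len(genes)))] + "*01"
        j_call = j_calls[int(rng.integers(0, len(j_calls)))] + "*01"
        r = Rearrangement(sequence_id="plant", v_call=v_call, j_call=j_call, junction_aa=junction)
        cands = _standard_candidates(r, catalog, clans)
        if cands and _best(cands)[1].subset_id == s.subset_id:
            used_junctions.add(junction)
            return cdr3, v_call, j_call, s.motif_offset
    raise PlantingError(f"could not construct a standard plant for subset {s.subset_id}")


def _build_satellite_plant(
    rng: np.random.Generator,
    s: SubsetDefinition,
    catalog: list[SubsetDefinition],
    clans: ClanMap,
    used_junctions: set[str],
    max_tries: int = 200,
) -> tuple[str, str, str, int]:
    """CDR3 satisfying the satellite — but not the standard — criteria for s."""
    L, m = s.cdr3_length, len(s.motif)
    combos = [
        (dl, do)
        for dl in range(-2, 3)
        for do in range(-2, 3)
        if not (dl == 0 and do == 0)
        and s.motif_offset + do >= 0
        and s.motif_offset + do + m <= L + dl
    ]
    if not combos:
        raise PlantingError(f"no feasible satellite perturbation for subset {s.subset_id}")
    genes = sorted(s.ighv_genes)
    j_calls = sorted(DEFAULT_J_STUBS)
    for attempt in range(max_tries):
        dl, do = combos[int(rng.integers(0, len(combos)))]
        new_len = L + dl
        o = s.motif_offset + do
        chars = []
        for i in range(new_len):
            if o <= i < o + m:
                p = s.motif[i - o]
                chars.append(s.consensus_cdr3[s.motif_offset + (i - o)] if p == "X" else p)
            else:
                j = i - do
                chars.append(s.consensus_cdr3[j] if 0 <= j < L else _rand_aa(rng, 1))
        free = [i for i in range(new_len) if not (o <= i < o + m)]
        n_uniq = min(1 + attempt // 20, len(free))
        if free:
            for i in rng.choice(len(free), size=n_uniq, replace=False):
                chars[free[i]] = _substitute(rng, chars[free[i]])
        cdr3 = "".join(chars)
        junction = f"C{cdr3}W"
        if junction in used_junctions:
            continue
        v_call = genes[int(rng.integers(0, len(genes)))] + "*01"
        j_call = j_calls[int(rng.integers(0, len(j_calls)))] + "*01"
        r = Rearrangement(sequence_id="plant", v_call=v_call, j_call=j_call, junction_aa=junction)
        if _standard_candidates(r, catalog, clans):
            continue
        cands = _satellite_candidates(r, catalog, clans)
        if cands and _best(cands)[1].subset_id == s.subset_id:
            used_junctions.add(junction)
            return cdr3, v_call, j_call, o
    raise PlantingError(f"could not construct a satellite plant for subset {s.subset_id}")


def _background_cdr3(
    rng: np.random.Generator,
    v_gene: str,
    d_core: str,
    j_stub: str,
    tdt_on: bool,
    mean_n: float,
) -> str:
    n1 = int(rng.poisson(mean_n)) if tdt_on else 0
    n2 = int(rng.poisson(mean_n)) if tdt_on else 0
    return _V_STUBS[v_gene] + _rand_aa(rng, n1) + d_core + _rand_aa(rng, n2) + j_stub


def simulate(
    config: SimConfig,
    catalog: list[SubsetDefinition],
    clans: ClanMap | None = None,
) -> tuple[list[Rearrangement], pd.DataFrame]:
    """Generate a multi-donor, multi-population repertoire plus ground truth.

    Returns the rearrangement list and a truth table with one row per
    planted sequence (sequence_id, sequence_key, subset_id, tier,
    sample_id, population, motif_start).
    """
    clans = clans or DEFAULT_CLAN_MAP
    by_id = {s.subset_id: s for s in catalog}
    for p in config.plantings:
        if p.subset_id not in by_id:
            raise ValueError(f"planting refers to unknown subset {p.subset_id!r}")

    rng = np.random.default_rng(config.seed)
    v_genes = sorted(config.v_usage)
    v_probs = np.array([config.v_usage[g] for g in v_genes], dtype=float)
    v_probs /= v_probs.sum()
    d_names = sorted(DEFAULT_D_CORES)
    j_names = sorted(DEFAULT_J_STUBS)

    cum = np.cumsum([p.frequency for p in config.plantings])
    used_junctions: set[str] = set()
    rearrangements: list[Rearrangement] = []
    truth_rows: list[dict] = []
    counter = 0

    for sample_idx in range(config.n_samples):
        sample_id = f"D{sample_idx + 1}"
        for pop in config.populations:
            u = rng.random(pop.n_unique)
            v_idx = rng.choice(len(v_genes), size=pop.n_unique, p=v_probs)
            d_idx = rng.integers(0, len(d_names), size=pop.n_unique)
            j_idx = rng.integers(0, len(j_names), size=pop.n_unique)
            for i in range(pop.n_unique):
                counter += 1
                seq_id = f"S{counter:07d}"
                plant_i = int(np.searchsorted(cum, u[i], side="right")) if len(cum) else len(cum)
                if plant_i < len(config.plantings) and u[i] < cum[-1]:
                    plant = config.plantings[plant_i]
                    subset = by_id[plant.subset_id]
                    if plant.tier == "standard":
                        cdr3, v_call, j_call, motif_start = _build_standard_plant(
                            rng, subset, catalog, clans, plant.shm_perturb, used_junctions
                        )
                    else:
                        cdr3, v_call, j_call, motif_start = _build_satellite_plant(
                            rng, subset, catalog, clans, used_junctions
                        )
                    r = Rearrangement(
                        sequence_id=seq_id,
                        v_call=v_call,
                        j_call=j_call,
                        junction_aa=f"C{cdr3}W",
                        d_call=d_names[d_idx[i]] + "*01",
                        v_identity=_v_identity(rng, pop.shm_rate),
                        sample_id=sample_id,
                        population=pop.label,
                    )
                    rearrangements.append(r)
                    truth_rows.append(
                        {
                            "sequence_id": seq_id,
                            "sequence_key": unique_key(r),
                            "subset_id": plant.subset_id,
                            "tier": plant.tier,
                            "sample_id": sample_id,
                            "population": pop.label,
                            "motif_start": motif_start,
                            "motif_length": len(subset.motif),
                        }
                    )
                else:
                    v_gene = v_genes[v_idx[i]]
                    cdr3 = _background_cdr3(
                        rng,
                        v_gene,
                        DEFAULT_D_CORES[d_names[d_idx[i]]],
                        DEFAULT_J_STUBS[j_names[j_idx[i]]],
                        pop.tdt_on,
                        config.mean_n_length,
                    )
                    cdr3 = _apply_shm(rng, cdr3, pop.shm_rate)
                    rearrangements.append(
                        Rearrangement(
                            sequence_id=seq_id,
                            v_call=v_gene + "*01",
                            j_call=j_names[j_idx[i]] + "*01",
                            junction_aa=f"C{cdr3}W",
                            d_call=d_names[d_idx[i]] + "*01",
                            v_identity=_v_identity(rng, pop.shm_rate),
                            sample_id=sample_id,
                            population=pop.label,
                        )
                    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "sequence_id",
            "sequence_key",
            "subset_id",
            "tier",
            "sample_id",
            "population",
            "motif_start",
            "motif_length",
        ],
    )
    return rearrangements, truth


def corrupt(
    rearrangements: list[Rearrangement],
    substitution_rate: float,
    seed: int = 0,
    truth: pd.DataFrame | None = None,
) -> list[Rearrangement]:
    """Random residue substitutions for robustness sweeps.

    Each CDR3 position is substituted (to a different residue) with the
    given probability; positions inside a planted motif (located via the
    truth table) are left untouched so that corruption probes the
    identity/similarity margins rather than trivially destroying motifs.
    """
    if not 0.0 <= substitution_rate <= 1.0:
        raise ValueError(f"substitution_rate must be in [0,1], got {substitution_rate}")
    protected: dict[str, range] = {}
    if truth is not None and len(truth):
        for row in truth.itertuples(index=False):
            protected[row.sequence_id] = range(
                int(row.motif_start), int(row.motif_start) + int(row.motif_length)
            )
    rng = np.random.default_rng(seed)
    out: list[Rearrangement] = []
    from dataclasses import replace

    for r in rearrangements:
        cdr3 = list(r.cdr3_aa)
        span = protected.get(r.sequence_id, range(0))
        changed = False
        for i in range(len(cdr3)):
            if i in span:
                continue
            if rng.random() < substitution_rate:
                cdr3[i] = _substitute(rng, cdr3[i])
                changed = True
        if changed:
            out.append(replace(r, junction_aa=f"C{''.join(cdr3)}W"))
        else:
            out.append(r)
    return out
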