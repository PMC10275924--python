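"""Forward Mendelian model of the *Aedes* sex locus with marker-transgene linkage.

In *Aedes* mosquitoes sex is controlled by a pair of non-homologous loci on
chromosome 1: females are m/m and males are m/M.  A fluorescent marker
transgene inserted near either locus co-segregates with it, so fluorescence
read at the first larval stage reports sex — the basis of a genetic sexing
strain (GSS).  Linkage is not absolute: a crossover between marker and sex
locus (probability ``r`` per meiosis, of order 1e-4 to 1e-3 in practice)
produces recombinant haplotypes, and in a sorting programme these set the
floor on female contamination of male release batches.

This module models haplotypes, genotypes and phenotypes of such strains,
exact gamete/offspring distributions under recombination, the two-strain
crossing scheme used to mass-produce non-transgenic males, stochastic cohort
realization, multi-generation colony maintenance under different sorting
policies, and exact-binomial estimation of the recombination rate from
screening counts.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "Haplotype",
    "Genotype",
    "Phenotype",
    "StrainSpec",
    "GameteDistribution",
    "OffspringDistribution",
    "CrossingSchemeResult",
    "ColonyState",
    "SortingPolicy",
    "ScreeningRecord",
    "RateEstimate",
    "register_fluorophore",
    "parse_haplotype",
    "parse_genotype",
    "gamete_distribution",
    "cross",
    "phenotype_of",
    "crossing_scheme",
    "contamination_closed_form",
    "simulate_cohort",
    "propagate_colony",
    "estimate_recombination_rate",
    "load_strains",
    "save_strains",
]

_PROB_TOL = 1e-12

# Fluorophores seen on COPAS-sortable constructs; extend via register_fluorophore().
_FLUOROPHORES = {"GFP", "eGFP", "YFP", "DsRed", "mTurquoise2", "mCherry", "CFP"}


def register_fluorophore(name: str) -> None:
    """Register an additional fluorophore marker name."""
    if not name or not isinstance(name, str):
        raise ValueError("fluorophore name must be a non-empty string")
    _FLUOROPHORES.add(name)


@dataclass(frozen=True)
class Haplotype:
    """One chromosome-1 haplotype: a sex allele and an optional linked marker.

    ``sex_allele`` is ``"M"`` (male-determining) or ``"m"``; ``marker`` is a
    registered fluorophore name or ``None``.
    """

    sex_allele: str
    marker: str | None = None

    def __post_init__(self):
        if self.sex_allele not in ("M", "m"):
            raise ValueError(f"sex_allele must be 'M' or 'm', got {self.sex_allele!r}")
        if self.marker is not None and self.marker not in _FLUOROPHORES:
            raise ValueError(
                f"unknown fluorophore {self.marker!r}; register it first"
            )

    @property
    def is_male_determining(self) -> bool:
        return self.sex_allele == "M"

    def __str__(self) -> str:
        return self.sex_allele if self.marker is None else f"{self.sex_allele}[{self.marker}]"


def parse_haplotype(text: str) -> Haplotype:
    """Parse bracket notation like ``"m[GFP]"`` or ``"M"``."""
    text = text.strip()
    if "[" in text:
        allele, rest = text.split("[", 1)
        if not rest.endswith("]"):
            raise ValueError(f"malformed haplotype {text!r}")
        return Haplotype(allele.strip(), rest[:-1].strip())
    return Haplotype(text)


@dataclass(frozen=True)
class Genotype:
    """An unordered pair of haplotypes.

    M/M is rejected: mothers never carry M, so no modelled cross can produce
    an M/M individual and such input indicates an upstream error.
    """

    haplotypes: tuple[Haplotype, Haplotype]

    def __init__(self, h1: Haplotype, h2: Haplotype):
        # canonical order writes the common allele first: m/M, m/m[GFP]
        pair = tuple(
            sorted((h1, h2), key=lambda h: (h.sex_allele != "m", h.marker or ""))
        )
        if sum(h.is_male_determining for h in pair) > 1:
            raise ValueError("M/M genotype is invalid (mothers never carry M)")
        object.__setattr__(self, "haplotypes", pair)

    @property
    def is_male(self) -> bool:
        return any(h.is_male_determining for h in self.haplotypes)

    @property
    def sex(self) -> str:
        return "male" if self.is_male else "female"

    def marker_copies(self) -> dict[str, int]:
        copies: Counter = Counter()
        for h in self.haplotypes:
            if h.marker is not None:
                copies[h.marker] += 1
        return dict(copies)

    def __str__(self) -> str:
        return "/".join(str(h) for h in self.haplotypes)


def parse_genotype(text: str) -> Genotype:
    """Parse notation like ``"m[GFP]/M"``."""
    parts = text.strip().split("/")
    if len(parts) != 2:
        raise ValueError(f"genotype must have exactly two haplotypes: {text!r}")
    return Genotype(parse_haplotype(parts[0]), parse_haplotype(parts[1]))


@dataclass(frozen=True)
class Phenotype:
    """Observable state: sex plus fluorophore copy numbers.

    Copy number matters on the sorter: two copies of a marker are brighter
    than one, so hemizygotes and homozygotes form distinct clouds.
    """

    sex: str
    fluorescence_copies: tuple[tuple[str, int], ...]

    @property
    def copies(self) -> dict[str, int]:
        return dict(self.fluorescence_copies)

    @property
    def is_fluorescent(self) -> bool:
        return len(self.fluorescence_copies) > 0

    def __str__(self) -> str:
        if not self.fluorescence_copies:
            return f"{self.sex}:nonfluorescent"
        marks = ",".join(f"{m}x{c}" for m, c in self.fluorescence_copies)
        return f"{self.sex}:{marks}"


def phenotype_of(g: Genotype) -> Phenotype:
    """Phenotype of a genotype: sex from M presence, copy counts from markers."""
    copies = tuple(sorted(g.marker_copies().items()))
    return Phenotype(sex=g.sex, fluorescence_copies=copies)


def _validated_probs(probs: Mapping, kind: str) -> dict:
    total = 0.0
    for key, p in probs.items():
        if p < -_PROB_TOL:
            raise ValueError(f"negative probability for {key}")
        total += p
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{kind} probabilities sum to {total}, not 1")
    return {k: float(p) for k, p in probs.items() if p > 0.0}


@dataclass(frozen=True)
class GameteDistribution:
    """Probability mass over haplotypes produced by one parent's meiosis."""

    probs: Mapping[Haplotype, float]

    def __post_init__(self):
        object.__setattr__(self, "probs", _validated_probs(self.probs, "gamete"))

    def items(self):
        return self.probs.items()

    def __getitem__(self, h: Haplotype) -> float:
        return self.probs.get(h, 0.0)


@dataclass(frozen=True)
class OffspringDistribution:
    """Probability mass over offspring genotypes from a cross."""

    probs: Mapping[Genotype, float]

    def __post_init__(self):
        object.__setattr__(self, "probs", _validated_probs(self.probs, "offspring"))

    def items(self):
        return self.probs.items()

    def __getitem__(self, g: Genotype) -> float:
        return self.probs.get(g, 0.0)

    def sex_fluorescence_partition(self) -> dict[Phenotype, float]:
        """Mass per (sex × fluorescence-class), the classes a sorter can gate."""
        part: Counter = Counter()
        for g, p in self.probs.items():
            part[phenotype_of(g)] += p
        return dict(part)

    def nonfluorescent_fraction(self) -> float:
        return sum(p for g, p in self.probs.items() if not g.marker_copies())

    def mass(self, predicate) -> float:
        return sum(p for g, p in self.probs.items() if predicate(g))


def _check_rate(r: float) -> float:
    if not 0.0 <= r <= 0.5:
        raise ValueError(f"recombination rate must be in [0, 0.5], got {r}")
    return float(r)


def gamete_distribution(parent: Genotype, recomb_rate: float) -> GameteDistribution:
    """Gamete haplotype distribution of one parent under recombination.

    Each parental haplotype is transmitted with probability (1-r)/2; the two
    recombinant haplotypes (markers swapped between the sex alleles) each with
    probability r/2.  If both haplotypes carry the same marker state the
    distribution collapses (recombination is invisible).
    """
    r = _check_rate(recomb_rate)
    h1, h2 = parent.haplotypes
    rec1 = Haplotype(h1.sex_allele, h2.marker)
    rec2 = Haplotype(h2.sex_allele, h1.marker)
    probs: Counter = Counter()
    probs[h1] += (1.0 - r) / 2.0
    probs[h2] += (1.0 - r) / 2.0
    probs[rec1] += r / 2.0
    probs[rec2] += r / 2.0
    return GameteDistribution(dict(probs))


ParentLike = Union[Genotype, OffspringDistribution]


def _parent_gametes(parent: ParentLike, r: float) -> dict[Haplotype, float]:
    if isinstance(parent, Genotype):
        return dict(gamete_distribution(parent, r).items())
    mix: Counter = Counter()
    for g, pg in parent.items():
        for h, ph in gamete_distribution(g, r).items():
            mix[h] += pg * ph
    return dict(mix)


def cross(
    mothers: ParentLike,
    fathers: ParentLike,
    r_mother: float = 0.0,
    r_father: float = 0.0,
) -> OffspringDistribution:
    """Offspring genotype distribution of a cross.

    Parents may be single genotypes or genotype distributions (e.g. a sorted
    fraction of a previous generation).  Recombination is applied
    independently in each parent's meiosis at that parent's rate.  The mother
    side must be free of M haplotypes.
    """
    mother_genos = [mothers] if isinstance(mothers, Genotype) else [g for g, _ in mothers.items()]
    for g in mother_genos:
        if g.is_male:
            raise ValueError(f"mother genotype {g} carries M; mothers must be m/m")
    mg = _parent_gametes(mothers, r_mother)
    fg = _parent_gametes(fathers, r_father)
    probs: Counter = Counter()
    for hm, pm in mg.items():
        for hf, pf in fg.items():
            probs[Genotype(hm, hf)] += pm * pf
    return OffspringDistribution(dict(probs))


@dataclass(frozen=True)
class StrainSpec:
    """A genetic sexing strain: canonical male/female genotypes and its
    marker-to-sex-locus recombination rate per meiosis."""

    name: str
    male_genotype: Genotype
    female_genotype: Genotype
    recomb_rate: float

    def __post_init__(self):
        _check_rate(self.recomb_rate)
        if self.female_genotype.is_male:
            raise ValueError("female_genotype must not carry M")
        if not self.male_genotype.is_male:
            raise ValueError("male_genotype must carry M")

    def canonical_phenotypes(self) -> tuple[Phenotype, Phenotype]:
        return phenotype_of(self.male_genotype), phenotype_of(self.female_genotype)


@dataclass(frozen=True)
class CrossingSchemeResult:
    """Outcome of the two-strain crossing scheme for non-transgenic males."""

    offspring: OffspringDistribution
    nonfluorescent_fraction: float
    female_contamination: float  # female fraction within the non-fluorescent class


def crossing_scheme(M_strain: StrainSpec, m_strain: StrainSpec) -> CrossingSchemeResult:
    """Cross non-transgenic females of an M-linked strain to hemizygous males
    of an m-linked strain.

    Non-fluorescent offspring are, up to recombination, non-transgenic males;
    the female fraction within that class is the contamination a fluorescence
    sorter cannot remove.
    """
    mother = M_strain.female_genotype
    if mother.marker_copies():
        raise ValueError(
            "crossing scheme mothers must be the non-transgenic females of the M strain"
        )
    father = m_strain.male_genotype
    copies = father.marker_copies()
    if not copies or any(c != 1 for c in copies.values()):
        raise ValueError(
            "crossing scheme fathers must be hemizygous marked males of the m strain"
        )
    off = cross(mother, father, r_mother=M_strain.recomb_rate, r_father=m_strain.recomb_rate)
    nonfluor = off.nonfluorescent_fraction()
    female_nonfluor = off.mass(lambda g: not g.is_male and not g.marker_copies())
    contamination = female_nonfluor / nonfluor if nonfluor > 0 else 0.0
    return CrossingSchemeResult(off, nonfluor, contamination)


def contamination_closed_form(recomb_rate: float) -> float:
    """Female fraction among non-fluorescent crossing-scheme offspring.

    With m/m mothers and m[marker]/M fathers the non-fluorescent class has
    mass (1-r)/2 (m/M males) + r/2 (m/m recombinant females) = 1/2, so the
    female fraction within it is exactly r.
    """
    return _check_rate(recomb_rate)


@dataclass
class ColonyState:
    """Integer genotype counts of one discrete generation."""

    generation: int
    counts: dict[Genotype, int]

    def __post_init__(self):
        if self.generation < 0:
            raise ValueError("generation must be >= 0")
        for g, c in self.counts.items():
            if c < 0 or c != int(c):
                raise ValueError(f"count for {g} must be a nonnegative integer")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def by_sex(self) -> tuple[dict[Genotype, int], dict[Genotype, int]]:
        females = {g: c for g, c in self.counts.items() if not g.is_male}
        males = {g: c for g, c in self.counts.items() if g.is_male}
        return females, males


def simulate_cohort(dist: OffspringDistribution, n: int, seed: int) -> ColonyState:
    """Multinomial realization of ``n`` offspring from a cross distribution."""
    if n < 0:
        raise ValueError("cohort size must be nonnegative")
    rng = np.random.default_rng(seed)
    genos = sorted(dist.probs, key=str)
    probs = np.array([dist.probs[g] for g in genos])
    draws = rng.multinomial(n, probs) if n > 0 else np.zeros(len(genos), dtype=int)
    return ColonyState(generation=0, counts={g: int(c) for g, c in zip(genos, draws)})


@dataclass(frozen=True)
class SortingPolicy:
    """Which offspring are retained as next-generation parents.

    mode:
      * ``"none"``      — retain by sex only (no fluorescence gate); recombinant
        lineages accumulate generation on generation.
      * ``"phenotype"`` — retain only individuals whose (sex, copy-number)
        phenotype matches the strain's canonical classes, i.e. per-generation
        fluorescence sorting.
      * ``"perfect"``   — phenotype sorting plus a perfect re-check that
        removes every non-canonical genotype (idealized visual filter).
    """

    mode: str = "phenotype"
    n_mothers: int = 100
    n_fathers: int = 100
    offspring_per_generation: int = 10_000

    def __post_init__(self):
        if self.mode not in ("none", "phenotype", "perfect"):
            raise ValueError(f"unknown sorting policy mode {self.mode!r}")


def _sample_counts(rng, pool: dict[Genotype, int], n: int) -> dict[Genotype, int]:
    """Draw n individuals without replacement from genotype counts."""
    genos = sorted(pool, key=str)
    counts = np.array([pool[g] for g in genos])
    total = int(counts.sum())
    if total <= n:
        return {g: int(c) for g, c in zip(genos, counts)}
    draw = rng.multivariate_hypergeometric(counts, n)
    return {g: int(c) for g, c in zip(genos, draw) if c > 0}


def propagate_colony(
    initial: ColonyState,
    strain: StrainSpec,
    generations: int,
    policy: SortingPolicy,
    seed: int,
) -> pd.DataFrame:
    """Simulate strain maintenance over discrete non-overlapping generations.

    Each generation the retained mothers and fathers are crossed (recombination
    at the strain rate in both meioses), a fixed-size offspring cohort is drawn,
    recombinant frequencies are recorded at sorting time, and parents for the
    next generation are retained according to ``policy``.

    Returns a table with one row per generation: cohort size, recombinant
    phenotype/genotype frequencies, and retained parent numbers.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    rng = np.random.default_rng(seed)
    canon_m, canon_f = strain.canonical_phenotypes()
    canon_geno = {strain.male_genotype, strain.female_genotype}
    canon_pheno = {canon_m, canon_f}

    def retain(counts: dict[Genotype, int]) -> dict[Genotype, int]:
        if policy.mode == "none":
            return counts
        if policy.mode == "phenotype":
            return {g: c for g, c in counts.items() if phenotype_of(g) in canon_pheno}
        return {g: c for g, c in counts.items() if g in canon_geno}

    # founders are sorted under the same policy as every later generation
    founders = retain(initial.counts)
    if not founders:
        raise RuntimeError("colony extinct at generation 0: empty retained class")
    state = ColonyState(generation=initial.generation, counts=founders)
    rows = []
    for gen in range(1, generations + 1):
        females, males = state.by_sex()
        mothers = _sample_counts(rng, females, policy.n_mothers)
        fathers = _sample_counts(rng, males, policy.n_fathers)
        if not mothers or not fathers:
            raise RuntimeError(f"colony extinct at generation {gen}: no retained parents")
        mdist = OffspringDistribution(
            {g: c / sum(mothers.values()) for g, c in mothers.items()}
        )
        fdist = OffspringDistribution(
            {g: c / sum(fathers.values()) for g, c in fathers.items()}
        )
        off = cross(mdist, fdist, strain.recomb_rate, strain.recomb_rate)
        cohort = simulate_cohort(off, policy.offspring_per_generation, int(rng.integers(2**31)))
        n = cohort.total
        rec_pheno = sum(
            c for g, c in cohort.counts.items() if phenotype_of(g) not in canon_pheno
        )
        rec_geno = sum(c for g, c in cohort.counts.items() if g not in canon_geno)
        rows.append(
            {
                "generation": gen,
                "n_offspring": n,
                "recombinant_phenotype_freq": rec_pheno / n if n else 0.0,
                "recombinant_genotype_freq": rec_geno / n if n else 0.0,
            }
        )

        retained = retain(cohort.counts)
        if not retained:
            raise RuntimeError(f"colony extinct at generation {gen}: empty retained class")
        state = ColonyState(generation=gen, counts=retained)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ScreeningRecord:
    """Recombinant screening outcome: ``n_recombinant`` seen in ``n_screened``."""

    n_screened: int
    n_recombinant: int

    def __post_init__(self):
        if self.n_screened <= 0:
            raise ValueError("n_screened must be positive")
        if not 0 <= self.n_recombinant <= self.n_screened:
            raise ValueError("n_recombinant must be in [0, n_screened]")


@dataclass(frozen=True)
class RateEstimate:
    point: float
    lower: float
    upper: float
    confidence: float


def estimate_recombination_rate(rec: ScreeningRecord, confidence: float = 0.95) -> RateEstimate:
    """Point estimate and exact (Clopper–Pearson) CI for a recombination rate.

    The exact binomial interval is used because observed rates are of order
    1e-4, far outside the validity of normal approximations.
    """
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    k, n = rec.n_recombinant, rec.n_screened
    alpha = 1.0 - confidence
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2.0, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return RateEstimate(point=k / n, lower=lower, upper=upper, confidence=confidence)


# ---------------------------------------------------------------------------
# Strain config I/O (bracket notation, YAML or JSON)

def _strain_to_dict(s: StrainSpec) -> dict:
    return {
        "male_genotype": str(s.male_genotype),
        "female_genotype": str(s.female_genotype),
        "recomb_rate": s.recomb_rate,
    }


def save_strains(strains: Mapping[str, StrainSpec], path: str | Path) -> None:
    path = Path(path)
    payload = {name: _strain_to_dict(s) for name, s in strains.items()}
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=True))


def load_strains(path: str | Path) -> dict[str, StrainSpec]:
    """Load strain definitions from a YAML/JSON config of the form::

        m-linked-GFP:
          male_genotype: "m[GFP]/M"
          female_genotype: "m[GFP]/m[GFP]"
          recomb_rate: 0.001
    """
    path = Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    strains = {}
    for name, entry in payload.items():
        strains[name] = StrainSpec(
            name=name,
            male_genotype=parse_genotype(entry["male_genotype"]),
            female_genotype=parse_genotype(entry["female_genotype"]),
            recomb_rate=float(entry["recomb_rate"]),
        )
    return strains
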