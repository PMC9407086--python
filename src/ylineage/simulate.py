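"""Forward-time Wright–Fisher simulator of male Y-chromosome lineages.

The model tracks a constant-size population of males.  Each generation
every individual draws a father uniformly at random from the previous
generation (haploid Wright–Fisher).  Each STR locus then mutates with its
per-generation rate under the single-step stepwise mutation model (±1
repeat with equal probability, reflecting at 1 repeat so alleles stay
positive).  Two rare event types add the structure seen in real
capillary-electrophoresis data:

* *microvariant* events attach a +0.2 fractional offset to an allele; the
  offset is inherited and survives later ±1-step mutations, mimicking
  stable lineage microvariants (e.g. the DYS518 ``.2`` alleles largely
  confined to one clade);
* *duplication* events convert a single-copy locus call into a two-allele
  list whose copies subsequently mutate independently (copy-number
  variants such as DYS19 15/16).

Haplogroup identity (the Y-SNP state) is inherited unchanged — Y-SNP
mutation rates are ~1e-9 per generation, five to seven orders of
magnitude below Y-STR rates, so on simulated time scales of 10²–10³
generations no SNP mutation is expected.  A run is fully deterministic
given its seed (one global RNG stream).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .haplogroups import HaplogroupTree, builtin_tree
from .panels import YFILER_PLATINUM, Panel
from .profiles import AlleleCall, SNPProfile, SNPState, STRProfile
from .rates import DEFAULT_MUTATION_RATES

__all__ = ["SimConfig", "SimOutput", "simulate_population", "simulate_divergent_pair"]


def _default_haplogroup_weights() -> dict[str, float]:
    # A plausible lower-Yangtze Han paternal mix: O-dominated with
    # O1a the largest single clade, moderate N and C2, minor D/QR.
    return {
        "O1a": 0.29,
        "O2a1": 0.13,
        "O2a2b": 0.14,
        "O2a2b1a1": 0.09,
        "O2a2a1a2": 0.04,
        "O2": 0.01,
        "O2a2": 0.01,
        "O1b": 0.04,
        "O1b2": 0.01,
        "C2": 0.07,
        "C": 0.01,
        "N": 0.09,
        "N1a1": 0.05,
        "QR": 0.02,
    }


# Modal repeat counts used to seed founder haplotypes, one per simulated
# allele column (multi-copy loci appear as their two copies).
_BASE_ALLELES: dict[str, float] = {
    "DYS19": 15, "DYS389I": 13, "DYS389II": 29, "DYS390": 24, "DYS391": 10,
    "DYS392": 14, "DYS393": 12, "DYS437": 14, "DYS438": 10, "DYS439": 12,
    "DYS448": 19, "DYS456": 15, "DYS458": 17, "DYS635": 21, "YGATAH4": 12,
    "DYS385a/b.1": 13, "DYS385a/b.2": 18,
    "DYS449": 30, "DYS460": 10, "DYS481": 22, "DYS518": 38, "DYS533": 11,
    "DYS570": 17, "DYS576": 18, "DYS627": 20,
    "DYF387S1a/b.1": 36, "DYF387S1a/b.2": 38,
    "DYS444": 12, "DYS447": 24, "DYS522": 11, "DYS549": 12, "DYS596": 12,
    "DYS612": 27, "DYS622": 23, "DYS643": 10, "DYS645": 8,
    "DYS527a/b.1": 21, "DYS527a/b.2": 23,
}


@dataclass
class SimConfig:
    """Parameters of one simulated population.

    Defaults emulate a regional population sample: a constant male
    effective size of 3000 (small enough for visible drift, large enough
    that a 150-male sample is dominated by singleton haplotypes, as real
    regional samples are), 200 generations of drift, per-locus mutation
    rates from the packaged table (4e-4 to 1.8e-2 per generation), and
    rare microvariant/duplication events.
    """

    n_founders: int = 3000
    n_generations: int = 200
    n_sample: int = 150
    founder_haplogroup_weights: dict[str, float] = field(
        default_factory=_default_haplogroup_weights
    )
    mutation_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MUTATION_RATES)
    )
    microvariant_rate: float = 1e-5
    duplication_rate: float = 1e-5
    split_generations: int = 100
    # optional unequal drift after the split (geographic isolation of one
    # daughter); None means both daughters drift split_generations
    split_generations_b: int | None = None
    # optional founder effect: daughter B is (re)founded from this many
    # lineages drawn from the ancestral population at the split
    founder_bottleneck_b: int | None = None
    seed: int = 0
    panel: Panel = field(default_factory=lambda: YFILER_PLATINUM)
    population: str = "sim"
    # optionally seed a clade-linked microvariant: every founder of the
    # given haplogroup starts with a +0.2 offset at the given locus
    clade_microvariant: tuple[str, str] | None = None

    def validate(self) -> None:
        if self.n_founders < 1:
            raise ValueError("n_founders must be >= 1")
        if self.n_generations < 0 or self.split_generations < 0:
            raise ValueError("generation counts must be >= 0")
        if self.split_generations_b is not None and self.split_generations_b < 0:
            raise ValueError("generation counts must be >= 0")
        if self.founder_bottleneck_b is not None and not (
            1 <= self.founder_bottleneck_b <= self.n_founders
        ):
            raise ValueError("founder_bottleneck_b must be in [1, n_founders]")
        if not (1 <= self.n_sample <= self.n_founders):
            raise ValueError("need 1 <= n_sample <= n_founders")
        w = self.founder_haplogroup_weights
        if not w or abs(sum(w.values()) - 1.0) > 1e-9:
            raise ValueError("founder haplogroup weights must sum to 1")
        if any(p < 0 or p > 1 for p in w.values()):
            raise ValueError("haplogroup weights must lie in [0, 1]")
        for name, rate in (
            ("microvariant_rate", self.microvariant_rate),
            ("duplication_rate", self.duplication_rate),
            *((f"mutation rate {l}", r) for l, r in self.mutation_rates.items()),
        ):
            if not (0.0 <= rate <= 0.1):
                raise ValueError(f"{name} out of range [0, 0.1]: {rate}")


@dataclass
class SimOutput:
    """Sampled STR + SNP profiles plus the simulation truth and event log."""

    str_profiles: list[STRProfile]
    snp_profiles: list[SNPProfile]
    true_haplogroups: dict[str, str]
    log: dict[str, float] = field(default_factory=dict)


class _PopState:
    """Vectorized population state: one row per male, one column per
    simulated allele copy."""

    def __init__(self, columns: list[str], loci: list[str], rates: np.ndarray,
                 dup_allowed: np.ndarray):
        self.columns = columns      # e.g. "DYS385a/b.1"
        self.loci = loci            # panel locus each column belongs to
        self.rates = rates
        self.dup_allowed = dup_allowed
        self.steps: np.ndarray | None = None      # int repeat counts
        self.frac: np.ndarray | None = None       # fractional offsets
        self.dup: np.ndarray | None = None        # duplication flags
        self.dup_steps: np.ndarray | None = None  # duplicated-copy repeats
        self.hg: np.ndarray | None = None         # haplogroup index

    def copy(self) -> "_PopState":
        other = _PopState(self.columns, self.loci, self.rates, self.dup_allowed)
        other.steps = self.steps.copy()
        other.frac = self.frac.copy()
        other.dup = self.dup.copy()
        other.dup_steps = self.dup_steps.copy()
        other.hg = self.hg.copy()
        return other


def _init_state(config: SimConfig, rng: np.random.Generator,
                hg_labels: list[str]) -> _PopState:
    columns, loci = [], []
    for locus in config.panel.loci:
        if config.panel.expected_copies[locus] == 2:
            columns.extend([f"{locus}.1", f"{locus}.2"])
            loci.extend([locus, locus])
        else:
            columns.append(locus)
            loci.append(locus)
    missing = [
        l for l in set(loci) if l not in config.mutation_rates
    ]
    if missing:
        raise KeyError(f"no mutation rate for loci: {sorted(missing)}")
    rates = np.array([config.mutation_rates[l] for l in loci])
    dup_allowed = np.array(
        [config.panel.expected_copies[l] == 1 for l in loci]
    )
    state = _PopState(columns, loci, rates, dup_allowed)

    n, L = config.n_founders, len(columns)
    base = np.array(
        [_BASE_ALLELES.get(c, _BASE_ALLELES.get(loci[i], 12))
         for i, c in enumerate(columns)]
    )
    weights = config.founder_haplogroup_weights
    labels = list(weights)
    probs = np.array([weights[l] for l in labels])
    hg_index = {l: hg_labels.index(l) for l in labels}
    draw = rng.choice(len(labels), size=n, p=probs / probs.sum())
    state.hg = np.array([hg_index[labels[d]] for d in draw])

    # founder diversity: haplogroup-specific offsets (so clades carry
    # distinct STR backgrounds) plus light per-founder jitter
    hg_offsets = rng.integers(-2, 3, size=(len(labels), L))
    jitter = rng.integers(-1, 2, size=(n, L)) * (rng.random((n, L)) < 0.3)
    state.steps = (base[None, :] + hg_offsets[draw] + jitter).astype(np.int64)
    state.steps = np.maximum(state.steps, 1)
    state.frac = np.zeros((n, L))
    state.dup = np.zeros((n, L), dtype=bool)
    state.dup_steps = np.zeros((n, L), dtype=np.int64)

    if config.clade_microvariant is not None:
        locus, clade = config.clade_microvariant
        col_mask = np.array([l == locus for l in state.loci])
        if not col_mask.any():
            raise KeyError(f"clade_microvariant locus {locus!r} not simulated")
        carriers = state.hg == hg_index[clade]
        state.frac[np.ix_(carriers, col_mask)] = 0.2
    return state


def _step_mutate(values: np.ndarray, mask: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Single-step SMM with reflection at 1 repeat."""
    delta = np.where(rng.random(values.shape) < 0.5, 1, -1)
    new = values + np.where(mask, delta, 0)
    # reflect: a -1 step from allele 1 becomes a +1 step
    reflect = new < 1
    new = np.where(reflect, values + np.where(mask, -delta, 0), new)
    return new


def _evolve(state: _PopState, generations: int, config: SimConfig,
            rng: np.random.Generator, log: dict[str, float]) -> None:
    n, L = state.steps.shape
    for _ in range(generations):
        fathers = rng.integers(0, n, size=n)
        for name in ("steps", "frac", "dup", "dup_steps", "hg"):
            setattr(state, name, getattr(state, name)[fathers])
        mut = rng.random((n, L)) < state.rates[None, :]
        state.steps = _step_mutate(state.steps, mut, rng)
        log["n_str_mutations"] += int(mut.sum())
        # duplicated copies mutate independently at the same locus rate
        if state.dup.any():
            mut_d = (rng.random((n, L)) < state.rates[None, :]) & state.dup
            state.dup_steps = _step_mutate(state.dup_steps, mut_d, rng)
            log["n_str_mutations"] += int(mut_d.sum())
        if config.microvariant_rate > 0:
            micro = rng.random((n, L)) < config.microvariant_rate
            state.frac = np.where(micro & (state.frac == 0), 0.2, state.frac)
            log["n_microvariant_events"] += int(micro.sum())
        if config.duplication_rate > 0:
            dup_new = (
                (rng.random((n, L)) < config.duplication_rate)
                & state.dup_allowed[None, :]
                & ~state.dup
            )
            state.dup_steps = np.where(dup_new, state.steps, state.dup_steps)
            state.dup |= dup_new
            log["n_duplication_events"] += int(dup_new.sum())
        log["n_lineage_generations"] += n


def _sample_profiles(state: _PopState, config: SimConfig,
                     rng: np.random.Generator, hg_labels: list[str],
                     tree: HaplogroupTree, population: str,
                     id_prefix: str) -> SimOutput:
    n = state.steps.shape[0]
    idx = rng.choice(n, size=config.n_sample, replace=False)
    str_profiles, snp_profiles = [], []
    true_hg: dict[str, str] = {}
    all_markers = tree.markers
    for rank, i in enumerate(idx):
        sample_id = f"{id_prefix}{rank:04d}"
        calls: dict[str, list[AlleleCall]] = {}
        for j, locus in enumerate(state.loci):
            value = state.steps[i, j] + state.frac[i, j]
            calls.setdefault(locus, []).append(AlleleCall(value))
            if state.dup[i, j]:
                calls[locus].append(
                    AlleleCall(state.dup_steps[i, j] + state.frac[i, j])
                )
        str_profiles.append(
            STRProfile(sample_id=sample_id, population=population, calls=calls)
        )
        label = hg_labels[state.hg[i]]
        derived = tree.derived_markers_for(label)
        states = {
            m: (SNPState.DERIVED if m in derived else SNPState.ANCESTRAL)
            for m in all_markers
        }
        snp_profiles.append(
            SNPProfile(sample_id=sample_id, population=population, states=states)
        )
        true_hg[sample_id] = label
    return SimOutput(
        str_profiles=str_profiles, snp_profiles=snp_profiles,
        true_haplogroups=true_hg,
    )


def simulate_population(config: SimConfig,
                        tree: HaplogroupTree | None = None) -> SimOutput:
    """Run one Wright–Fisher population and sample ``n_sample`` males."""
    config.validate()
    if tree is None:
        tree = builtin_tree()
    hg_labels = tree.labels
    for label in config.founder_haplogroup_weights:
        if label not in tree:
            raise KeyError(f"founder haplogroup {label!r} not in tree")
    rng = np.random.default_rng(config.seed)
    log = {
        "n_str_mutations": 0, "n_microvariant_events": 0,
        "n_duplication_events": 0, "n_lineage_generations": 0,
    }
    state = _init_state(config, rng, hg_labels)
    _evolve(state, config.n_generations, config, rng, log)
    out = _sample_profiles(
        state, config, rng, hg_labels, tree, config.population,
        f"{config.population}_",
    )
    out.log = log
    return out


def simulate_divergent_pair(config: SimConfig,
                            tree: HaplogroupTree | None = None
                            ) -> tuple[SimOutput, SimOutput]:
    """Simulate two populations that split ``config.split_generations``
    generations ago from a common ancestral population.

    The ancestral population evolves for ``n_generations``, is copied at
    the split, and each daughter then evolves independently for
    ``split_generations`` more generations.  With ``split_generations=0``
    both samples are drawn from the same gene pool, so any between-group
    differentiation statistic should be indistinguishable from zero.
    """
    config.validate()
    if tree is None:
        tree = builtin_tree()
    hg_labels = tree.labels
    rng = np.random.default_rng(config.seed)
    log = {
        "n_str_mutations": 0, "n_microvariant_events": 0,
        "n_duplication_events": 0, "n_lineage_generations": 0,
    }
    state = _init_state(config, rng, hg_labels)
    _evolve(state, config.n_generations, config, rng, log)
    split_b = (
        config.split_generations if config.split_generations_b is None
        else config.split_generations_b
    )
    outputs = []
    for suffix, n_gens in (("A", config.split_generations), ("B", split_b)):
        daughter = state.copy()
        if suffix == "B" and config.founder_bottleneck_b is not None:
            founders = rng.choice(
                config.n_founders, size=config.founder_bottleneck_b, replace=False
            )
            rows = rng.choice(founders, size=config.n_founders)
            for name in ("steps", "frac", "dup", "dup_steps", "hg"):
                setattr(daughter, name, getattr(daughter, name)[rows])
        _evolve(daughter, n_gens, config, rng, log)
        name = f"{config.population}{suffix}"
        out = _sample_profiles(
            daughter, config, rng, hg_labels, tree, name, f"{name}_"
        )
        out.log = dict(log)
        outputs.append(out)
    return outputs[0], outputs[1]
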