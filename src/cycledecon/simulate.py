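"""Synthetic synchronized-cell time courses with known temporal components.

The generator emulates a bulk RNA-seq time course of cells released from
cell-cycle arrest: 14 equally spaced samples spanning roughly two cycles,
two oscillatory gene programs offset by half a period (G1-S-like and
G2-M-like), and one transient program confined to the first cycle
(immediate-early-like).  Each sample's expression profile is a convex
mixture of the three component gene-probability distributions; sequencing
is modeled as a single multinomial draw per sample.  A paired unspliced
layer reproduces the maturation delay: unspliced abundance at time t
follows the spliced expectation at time t + d (clamped at the course end),
scaled by a global unspliced fraction.

Ground truth (mixing proportions, gene labels, delay) is returned alongside
the counts so that every downstream estimator can be tested for parameter
recovery.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import SplicedUnsplicedSet, TimeCourseMatrix, GeneSet

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "component_profiles",
    "simulate_timecourse",
    "cycling_gene_set",
]

COMPONENTS = ("osc_A", "osc_B", "transient")

# fraction of each topic's probability mass placed on its own genes /
# leaked onto the other components' genes / spread over background genes
_OWN_MASS = 0.918
_LEAK_MASS = 0.002
_BACKGROUND_MASS = 0.08


class InvalidConfigError(ValueError):
    """Raised for a simulation configuration that violates its invariants."""


@dataclass
class SimConfig:
    """Configuration of the synthetic time course.

    Attributes
    ----------
    n_samples : int
        Number of equally spaced time points (the emulated design uses 14).
    n_cycles : int
        Whole oscillation cycles spanned by the course (default 2).
    n_genes_per_component : int
        Genes assigned to each of the three components.
    n_background_genes : int
        Genes with uniform membership across components (no temporal signal
        beyond the shared mixture).
    n_lowcount_genes : int
        Genes whose expected totals fall below the low-count filter.
    total_counts_per_sample : int
        Library size N_t of each sample (spliced layer).
    unspliced_fraction : float
        Global scale of the unspliced layer relative to spliced, in (0, 1).
    delay_intervals : int
        Maturation delay d in sampling intervals: the unspliced expectation
        at index t equals the spliced expectation at index t + d (clamped).
    transient_decay : float
        Exponential decay constant tau of the transient component, in
        sampling intervals; must be positive.
    phase_offset : float
        Phase offset between the two oscillatory components as a fraction
        of a period (0.5 = anti-phase).
    noise_mode : str
        ``"multinomial"`` draws counts; ``"expectation"`` returns the exact
        expected values (deterministic end to end).
    seed : int
        Seed of the generator; identical seeds give bit-identical output.
    """

    n_samples: int = 14
    n_cycles: int = 2
    n_genes_per_component: int = 100
    n_background_genes: int = 200
    n_lowcount_genes: int = 50
    total_counts_per_sample: int = 1_000_000
    unspliced_fraction: float = 0.25
    delay_intervals: int = 1
    transient_decay: float = 3.0
    phase_offset: float = 0.5
    noise_mode: str = "multinomial"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise InvalidConfigError("n_samples must be >= 4")
        if 2 * self.n_cycles > self.n_samples:
            raise InvalidConfigError("need 2 * n_cycles <= n_samples to resolve the oscillation")
        if self.transient_decay <= 0:
            raise InvalidConfigError("transient_decay (tau) must be positive")
        if self.total_counts_per_sample <= 0:
            raise InvalidConfigError("total_counts_per_sample must be positive")
        if not (0.0 < self.unspliced_fraction < 1.0):
            raise InvalidConfigError("unspliced_fraction must lie in (0, 1)")
        if self.delay_intervals < 0 or self.delay_intervals >= self.n_samples:
            raise InvalidConfigError("delay_intervals must satisfy 0 <= d < n_samples")
        if self.noise_mode not in ("multinomial", "expectation"):
            raise InvalidConfigError("noise_mode must be 'multinomial' or 'expectation'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated time course.

    ``component_proportions`` holds the true per-sample mixing weights
    (rows on the simplex, columns ordered osc_A, osc_B, transient);
    ``gene_component`` labels every simulated gene with exactly one of
    osc_A / osc_B / transient / background / lowcount.
    """

    component_proportions: pd.DataFrame
    gene_component: dict[str, str]
    delay_intervals: int
    seed: int
    gene_topic_probs: pd.DataFrame | None = field(default=None, repr=False)

    def genes_of(self, label: str) -> list[str]:
        return [g for g, lab in self.gene_component.items() if lab == label]

    @property
    def oscillatory_genes(self) -> list[str]:
        return [g for g, lab in self.gene_component.items() if lab in ("osc_A", "osc_B")]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "component_proportions": {
                "samples": list(self.component_proportions.index),
                "components": list(self.component_proportions.columns),
                "values": self.component_proportions.to_numpy().tolist(),
            },
            "gene_component": self.gene_component,
            "delay_intervals": self.delay_intervals,
            "seed": self.seed,
        }
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(payload, indent=1))


def component_profiles(config: SimConfig) -> pd.DataFrame:
    """True per-sample component proportions (n_samples x 3, rows on simplex).

    Raw weights at sample index t (0-based, n = n_samples):

    - osc_A:     (1 + cos(2*pi*n_cycles*t/n)) / 2
    - osc_B:     (1 + cos(2*pi*n_cycles*t/n - 2*pi*phase_offset)) / 2
    - transient: exp(-t / tau)

    Each row is normalized to sum to one.
    """
    n = config.n_samples
    t = np.arange(n, dtype=float)
    theta = 2.0 * np.pi * config.n_cycles * t / n
    w_a = (1.0 + np.cos(theta)) / 2.0
    w_b = (1.0 + np.cos(theta - 2.0 * np.pi * config.phase_offset)) / 2.0
    w_t = np.exp(-t / config.transient_decay)
    raw = np.column_stack([w_a, w_b, w_t])
    props = raw / raw.sum(axis=1, keepdims=True)
    samples = [f"D{i + 1}" for i in range(n)]
    return pd.DataFrame(props, index=samples, columns=list(COMPONENTS))


def _gene_ids(config: SimConfig) -> tuple[list[str], dict[str, str]]:
    names: list[str] = []
    labels: dict[str, str] = {}
    for comp, prefix in zip(COMPONENTS, ("OSCA", "OSCB", "TRAN")):
        for i in range(config.n_genes_per_component):
            g = f"{prefix}_{i + 1:04d}"
            names.append(g)
            labels[g] = comp
    for i in range(config.n_background_genes):
        g = f"BG_{i + 1:04d}"
        names.append(g)
        labels[g] = "background"
    for i in range(config.n_lowcount_genes):
        g = f"LOW_{i + 1:04d}"
        names.append(g)
        labels[g] = "lowcount"
    return names, labels


def _gene_topic_probs(config: SimConfig, rng: np.random.Generator,
                      genes: list[str], labels: dict[str, str]) -> pd.DataFrame:
    """Gene-by-topic probability columns F (each column sums to 1).

    Each component's genes carry most of that component's mass (flat
    Dirichlet within the component), a small uniform leak covers the other
    components' genes, and background genes get identical mass in every
    column (uniform membership).  Low-count genes are excluded here; their
    expectations are appended separately.
    """
    main = [g for g in genes if labels[g] != "lowcount"]
    n_bg = sum(1 for g in main if labels[g] == "background")
    f = pd.DataFrame(0.0, index=main, columns=list(COMPONENTS))
    for comp in COMPONENTS:
        own = [g for g in main if labels[g] == comp]
        others = [g for g in main if labels[g] not in (comp, "background")]
        f.loc[own, comp] = rng.dirichlet(np.ones(len(own))) * _OWN_MASS
        if others:
            f.loc[others, comp] = _LEAK_MASS / len(others)
        if n_bg:
            f.loc[f.index[[labels[g] == "background" for g in main]], comp] = (
                _BACKGROUND_MASS / n_bg
            )
    # exact column normalization (guards rounding of the fixed masses)
    f = f / f.sum(axis=0)
    return f


def simulate_timecourse(config: SimConfig) -> tuple[SplicedUnsplicedSet, SyntheticTruth]:
    """Simulate a spliced/unspliced time course with known structure.

    Returns the aligned count layers plus the :class:`SyntheticTruth` used
    to generate them.  With ``noise_mode="expectation"`` the matrices hold
    the exact expected values and the run is fully deterministic; with
    ``noise_mode="multinomial"`` each sample is a single multinomial draw
    whose column total equals the configured library size exactly.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    d = config.delay_intervals
    props = component_profiles(config)
    genes, labels = _gene_ids(config)
    f = _gene_topic_probs(config, rng, genes, labels)

    # expected spliced profile of the structured genes: N_t * sum_c l_tc f_gc
    expected_main = config.total_counts_per_sample * (f.to_numpy() @ props.to_numpy().T)

    # low-count genes: flat temporal profile with expected course totals
    # uniformly in [2, 8), i.e. safely below the filter threshold of 10
    low_genes = [g for g in genes if labels[g] == "lowcount"]
    if low_genes:
        low_totals = rng.uniform(2.0, 8.0, size=len(low_genes))
        expected_low = np.tile((low_totals / n)[:, None], (1, n))
        expected_spliced = np.vstack([expected_main, expected_low])
    else:
        expected_spliced = expected_main
    all_genes = [g for g in genes if labels[g] != "lowcount"] + low_genes

    # unspliced expectation: spliced expectation at index t + d, clamped at
    # the last sample (the course is not circular), scaled globally
    shifted_idx = np.minimum(np.arange(n) + d, n - 1)
    expected_unspliced = config.unspliced_fraction * expected_spliced[:, shifted_idx]

    if config.noise_mode == "expectation":
        spliced_vals = expected_spliced
        unspliced_vals = expected_unspliced
    else:
        n_u = int(round(config.unspliced_fraction * config.total_counts_per_sample))
        spliced_vals = np.empty_like(expected_spliced)
        unspliced_vals = np.empty_like(expected_unspliced)
        for t in range(n):
            p_s = expected_spliced[:, t] / expected_spliced[:, t].sum()
            spliced_vals[:, t] = rng.multinomial(config.total_counts_per_sample, p_s)
            p_u = expected_unspliced[:, t] / expected_unspliced[:, t].sum()
            unspliced_vals[:, t] = rng.multinomial(n_u, p_u)

    samples = list(props.index)
    spliced = TimeCourseMatrix(pd.DataFrame(spliced_vals, index=all_genes, columns=samples),
                               layer="spliced")
    unspliced = TimeCourseMatrix(pd.DataFrame(unspliced_vals, index=all_genes, columns=samples),
                                 layer="unspliced")
    truth = SyntheticTruth(
        component_proportions=props,
        gene_component={g: labels[g] for g in all_genes},
        delay_intervals=d,
        seed=config.seed,
        gene_topic_probs=f,
    )
    return SplicedUnsplicedSet(spliced=spliced, unspliced=unspliced), truth


def cycling_gene_set(truth: SyntheticTruth, n_genes: int = 67,
                     name: str = "core_cycling") -> GeneSet:
    """A gene set of oscillatory genes mixing both phases about 2:1.

    Mirrors curated core cell-cycle sets, in which the late-phase (G2-M
    like) program contributes roughly twice as many genes as the early
    (G1-S like) one.  The imbalance matters: the two synthetic oscillatory
    programs are exact anti-phase cosines, so a phase-balanced average
    would cancel the oscillation entirely and leave the spliced/unspliced
    lag unidentifiable from the averaged signal -- a degeneracy real core
    sets avoid through unequal phase membership and heterogeneous phases.
    """
    a = truth.genes_of("osc_A")
    b = truth.genes_of("osc_B")
    n_major = min(int(np.ceil(2 * n_genes / 3)), len(a))
    picked = a[:n_major] + b[: n_genes - n_major]
    if len(picked) < n_genes:
        raise InvalidConfigError(
            f"not enough oscillatory genes ({len(a) + len(b)}) for a {n_genes}-gene set"
        )
    return GeneSet(name=name, genes=picked, description="synthetic oscillatory genes")
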