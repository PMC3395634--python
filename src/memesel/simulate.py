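"""Seeded codon-alignment simulation under site-wise selection regimes.

Sites are generated independently. Each site is either *constant*
(one (alpha, omega) pair on every branch) or *episodic*: every branch
independently draws the positively selected rate ``alpha * omega_plus``
with probability ``q_plus`` and the background rate ``alpha *
omega_minus`` otherwise. The strict-neutral null used for type-I-error
studies and for parametric bootstrap calibration of the test statistic
is the constant scenario with alpha = omega = 1 on every branch.

States are sampled exactly at branch endpoints from the transition
matrix (no within-branch stepping is needed because the process is
observed only at nodes). Each site gets its own RNG stream derived from
(master seed, site index), so results do not depend on evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import CodonAlignment
from .frequencies import FrequencyModel
from .genetic_code import GeneticCode, get_genetic_code
from .phylo import Branch, Phylogeny
from .rate_matrix import CodonModelKernel, NucleotideExchangeabilities


@dataclass(frozen=True)
class ConstantSite:
    """One (alpha, omega) pair shared by every branch."""

    alpha: float = 1.0
    omega: float = 1.0


@dataclass(frozen=True)
class EpisodicSite:
    """Branch-wise random draw between omega_minus and omega_plus."""

    alpha: float = 1.0
    omega_minus: float = 0.0
    omega_plus: float = 10.0
    q_plus: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.q_plus <= 1.0:
            raise ValueError("q_plus must lie in [0, 1]")


SiteSpec = ConstantSite | EpisodicSite


def default_theta() -> NucleotideExchangeabilities:
    """Mildly transition-biased GTR exchangeabilities for synthetic data."""
    return NucleotideExchangeabilities(
        ac=0.45, ag=1.0, at=0.25, cg=0.35, ct=1.05, gt=0.30
    )


def default_freqs() -> FrequencyModel:
    """Gently skewed position-specific frequencies for synthetic data."""
    return FrequencyModel(
        np.array(
            [
                [0.29, 0.20, 0.29, 0.22],
                [0.27, 0.24, 0.21, 0.28],
                [0.23, 0.27, 0.26, 0.24],
            ]
        )
    )


def balanced_tree(
    n_taxa: int,
    seed: int | np.random.Generator = 0,
    length_range: tuple[float, float] = (0.05, 0.3),
) -> Phylogeny:
    """Balanced binary topology with i.i.d. Uniform branch lengths.

    Taxa are named T01, T02, ...; lengths are expected substitutions per
    codon site. ``n_taxa`` must be a power of two.
    """
    if n_taxa < 2 or (n_taxa & (n_taxa - 1)) != 0:
        raise ValueError("n_taxa must be a power of two >= 2")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    width = len(str(n_taxa))
    names = [f"T{i + 1:0{width}d}" for i in range(n_taxa)]

    def newick(lo: int, hi: int) -> str:
        if hi - lo == 1:
            return names[lo]
        mid = (lo + hi) // 2
        return f"({newick(lo, mid)},{newick(mid, hi)})"

    from .phylo import parse_newick

    tree = parse_newick(newick(0, n_taxa) + ";")
    lengths = rng.uniform(*length_range, size=tree.n_branches)
    return tree.with_branch_lengths(lengths)


@dataclass
class SimulationScenario:
    """Everything needed to simulate one alignment reproducibly."""

    tree: Phylogeny
    sites: list[SiteSpec]
    theta: NucleotideExchangeabilities = field(default_factory=default_theta)
    freqs: FrequencyModel = field(default_factory=default_freqs)
    code: GeneticCode = field(default_factory=get_genetic_code)
    seed: int = 0
    scale: float | None = None  # default: unit mean rate at alpha=omega=1

    def kernel(self) -> CodonModelKernel:
        k = CodonModelKernel(self.code, self.theta, self.freqs, 1.0)
        scale = self.scale if self.scale is not None else 1.0 / k.mean_rate(1.0, 1.0)
        return CodonModelKernel(self.code, self.theta, self.freqs, scale)


@dataclass
class SiteTruth:
    site: int  # 1-based
    kind: str  # "constant" | "episodic"
    alpha: float
    omega_minus: float
    omega_plus: float
    q_plus: float
    plus_branches: list[str]

    @property
    def under_selection(self) -> bool:
        """Whether the generating process includes an omega > 1 regime
        actually drawn on at least one branch (episodic) or throughout
        (constant)."""
        if self.kind == "constant":
            return self.omega_plus > 1.0
        return self.omega_plus > 1.0 and len(self.plus_branches) > 0


def _category_stacks(
    kernel: CodonModelKernel, tree: Phylogeny, spec: SiteSpec
) -> list[np.ndarray]:
    times = np.array([b.length for b in tree.branches])
    if isinstance(spec, ConstantSite):
        return [kernel.transition_stack(spec.alpha, spec.alpha * spec.omega, times)]
    return [
        kernel.transition_stack(spec.alpha, spec.alpha * spec.omega_minus, times),
        kernel.transition_stack(spec.alpha, spec.alpha * spec.omega_plus, times),
    ]


def simulate_site(
    spec: SiteSpec,
    tree: Phylogeny,
    kernel: CodonModelKernel,
    rng: np.random.Generator,
    site_index: int = 1,
    stacks: list[np.ndarray] | None = None,
) -> tuple[dict[str, frozenset[int]], SiteTruth]:
    """Evolve one codon site down the tree; returns the leaf column and
    the truth record of per-branch category draws."""
    if stacks is None:
        stacks = _category_stacks(kernel, tree, spec)
    n = kernel.code.n_states
    state = {tree.root: int(rng.choice(n, p=kernel.pi))}
    episodic = isinstance(spec, EpisodicSite)
    plus_branches: list[str] = []
    for v in reversed(tree.postorder):
        for c in tree.children[v]:
            b = tree.branch_of_child(c)
            cat = 0
            if episodic and rng.random() < spec.q_plus:
                cat = 1
                plus_branches.append(b.name)
            p_row = stacks[cat][b.id][state[v]]
            state[c] = int(rng.choice(n, p=p_row))
    col = {
        tree.names[v]: frozenset([state[v]])
        for v in tree.postorder
        if tree.is_leaf[v]
    }
    truth = SiteTruth(
        site=site_index,
        kind="episodic" if episodic else "constant",
        alpha=spec.alpha,
        omega_minus=spec.omega_minus if episodic else spec.omega,
        omega_plus=spec.omega_plus if episodic else spec.omega,
        q_plus=spec.q_plus if episodic else 0.0,
        plus_branches=plus_branches,
    )
    return col, truth


def simulate_alignment(
    scenario: SimulationScenario,
) -> tuple[CodonAlignment, pd.DataFrame]:
    """Column-independent simulation of a whole alignment.

    Returns the codon alignment and a truth table (one row per site)
    recording the generating regime and the branches that drew the
    positively selected category.
    """
    kernel = scenario.kernel()
    tree = scenario.tree
    stack_cache: dict[SiteSpec, list[np.ndarray]] = {}
    columns = []
    truths = []
    for s, spec in enumerate(scenario.sites):
        if spec not in stack_cache:
            stack_cache[spec] = _category_stacks(kernel, tree, spec)
        rng = np.random.default_rng(
            np.random.SeedSequence([int(scenario.seed), s])
        )
        col, truth = simulate_site(
            spec, tree, kernel, rng, site_index=s + 1, stacks=stack_cache[spec]
        )
        columns.append(col)
        truths.append(truth)
    aln = CodonAlignment(
        names=[tree.names[v] for v in tree.postorder if tree.is_leaf[v]],
        columns=columns,
        code=scenario.code,
    )
    truth_df = pd.DataFrame(
        {
            "site": [t.site for t in truths],
            "kind": [t.kind for t in truths],
            "alpha": [t.alpha for t in truths],
            "omega_minus": [t.omega_minus for t in truths],
            "omega_plus": [t.omega_plus for t in truths],
            "q_plus": [t.q_plus for t in truths],
            "n_plus_branches": [len(t.plus_branches) for t in truths],
            "plus_branches": ["|".join(t.plus_branches) for t in truths],
            "under_selection": [t.under_selection for t in truths],
        }
    )
    return aln, truth_df


def alignment_to_sequences(aln: CodonAlignment) -> dict[str, str]:
    """Render an unambiguous codon alignment back to nucleotide strings."""
    sense = aln.code.sense_codons
    out = {}
    for name in aln.names:
        codons = []
        for col in aln.columns:
            states = col[name]
            if len(states) != 1:
                raise ValueError("ambiguous column cannot be rendered to FASTA")
            codons.append(sense[next(iter(states))])
        out[name] = "".join(codons)
    return out


@dataclass
class ErrorRates:
    fpr: float
    fpr_se: float
    n_null: int
    power: float
    power_se: float
    n_selected: int


def estimate_error_rates(
    truth: pd.DataFrame, pvalues: np.ndarray, p_threshold: float = 0.05
) -> ErrorRates:
    """Empirical false positive rate and power at a p-value threshold.

    Null sites are those whose generating regime never includes omega > 1
    on a drawn branch; selected sites are the rest.
    """
    p = np.asarray(pvalues, dtype=float)
    if len(p) != len(truth):
        raise ValueError("truth table and p-value vector differ in length")
    sel = truth["under_selection"].to_numpy(dtype=bool)
    reject = p <= p_threshold

    def rate(mask):
        n = int(mask.sum())
        if n == 0:
            return 0.0, 0.0, 0
        r = float(reject[mask].mean())
        return r, float(np.sqrt(r * (1 - r) / n)), n

    fpr, fpr_se, n_null = rate(~sel)
    power, power_se, n_sel = rate(sel)
    return ErrorRates(fpr, fpr_se, n_null, power, power_se, n_sel)
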