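"""Generators for synthetic inputs with the statistical structure the
analysis assumes.

Every pipeline stage can be exercised offline: protein alignments are
evolved along a chronogram under the same gamma+invariant JTT mixture the
likelihood machinery assumes (per-site rate category fixed across the whole
tree), FP saturation/displacement curves come from the exact binding
equilibria with additive Gaussian mP noise, and ITC isotherms from the 1:1
Wiseman model with per-injection noise.  Each generator records its ground
truth and seed so recovery tests can compare estimate against generating
value.  The packaged table of measured extant affinities is exposed here as
well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import binding as _binding
from .affinity_report import AffinityTable
from .asr import Alignment
from .evo_models import AMINO_ACIDS, SpectralRateMatrix, SubstitutionModel, build_rate_matrix
from .phylo import TimeTree, TreeNode, duplicate_clade


@dataclass
class SimulationTruth:
    """Ground truth of a synthetic dataset (sequence or binding flavour)."""

    seed: int
    # sequence-evolution truth
    ancestral_sequences: dict[int, str] | None = None
    site_categories: np.ndarray | None = None
    alpha: float | None = None
    p_inv: float | None = None
    branch_scale: float | None = None
    # binding truth
    binding_params: dict | None = None


# ---------------------------------------------------------------------------
# Trees


def random_chronogram(
    n_leaves: int,
    height: float = 100.0,
    seed: int = 0,
    prefix: str = "T",
) -> TimeTree:
    """A random ultrametric tree of the given height (My).

    Topology by recursive random bipartition; each internal node's age is a
    uniform fraction of its parent's age, which yields chronogram-like
    branch-length variation without modelling any particular speciation
    process.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    labels = [f"{prefix}{i+1}" for i in range(n_leaves)]

    def build(names: list[str], age: float) -> TreeNode:
        if len(names) == 1:
            return TreeNode(label=names[0], length=age)
        k = int(rng.integers(1, len(names)))
        left, right = names[:k], names[k:]
        child_age_l = age * rng.uniform(0.2, 0.9) if len(left) > 1 else 0.0
        child_age_r = age * rng.uniform(0.2, 0.9) if len(right) > 1 else 0.0
        node = TreeNode()
        for part, child_age in ((left, child_age_l), (right, child_age_r)):
            sub = build(part, child_age)
            sub.length = age - child_age if len(part) > 1 else age
            node.add_child(sub)
        return node

    order = list(rng.permutation(n_leaves))
    root = build([labels[i] for i in order], height)
    root.length = None
    return TimeTree(root)


#: Ages (My) used by the study-shaped example tree below.
ROOT_AGE_MY = 430.0
TELEOST_STEM_PARENT_AGE_MY = 380.0
TELEOST_CROWN_AGE_MY = 250.0
WGD_AGE_MY = 303.0


def example_fish_chronogram(
    n_teleost: int = 27,
    n_outgroup: int = 8,
    seed: int = 0,
) -> tuple[TimeTree, int]:
    """A fish-phylogeny-shaped chronogram for simulation studies.

    Returns ``(tree, teleost_crown_id)``: a root at 430 My with an outgroup
    clade and a teleost-like clade whose crown sits at 250 My below a stem
    reaching 380 My, so the 303 My whole-genome-duplication age lies on the
    crown's parent edge.  Duplicating the teleost clade at 303 My with
    :func:`p53evo.phylo.duplicate_clade` yields ``2*n_teleost + n_outgroup``
    leaves (62 with the defaults, matching a two-paralog fish alignment).
    """
    rng = np.random.default_rng(seed)
    out_sub = random_chronogram(
        n_outgroup, height=TELEOST_STEM_PARENT_AGE_MY, seed=int(rng.integers(2**31)),
        prefix="out",
    )
    tel_sub = random_chronogram(
        n_teleost, height=TELEOST_CROWN_AGE_MY, seed=int(rng.integers(2**31)),
        prefix="tel",
    )
    root = TreeNode()
    out_root = out_sub.root
    out_root.length = ROOT_AGE_MY - TELEOST_STEM_PARENT_AGE_MY
    root.add_child(out_root)
    tel_root = tel_sub.root
    tel_root.length = ROOT_AGE_MY - TELEOST_CROWN_AGE_MY
    tel_root.node_id = 1
    root.add_child(tel_root)
    tree = TimeTree(root)
    return tree, 1


def duplicated_fish_chronogram(
    n_teleost: int = 27,
    n_outgroup: int = 8,
    seed: int = 0,
    wgd_age: float = WGD_AGE_MY,
) -> TimeTree:
    """The example chronogram with its teleost clade duplicated at the WGD age."""
    tree, crown = example_fish_chronogram(n_teleost, n_outgroup, seed)
    return duplicate_clade(tree, crown, wgd_age)


# ---------------------------------------------------------------------------
# Sequence evolution


def simulate_alignment(
    tree: TimeTree,
    model: SubstitutionModel,
    n_sites: int,
    seed: int,
    branch_scale: float = 0.002,
) -> tuple[Alignment, SimulationTruth]:
    """Evolve an alignment along ``tree`` under ``model``.

    Root residues are drawn from the stationary frequencies; each site draws
    one rate category (invariant with probability ``p_invariant``, otherwise
    a gamma category) that applies on every branch; states then evolve via
    the model's transition probabilities with branch lengths
    ``length * branch_scale`` (expected substitutions per site; the default
    0.002/My is a typical disordered-protein rate on a My-scaled tree).
    All internal-node states are recorded as ground truth.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    rng = np.random.default_rng(seed)
    tree.assign_node_ids(start=len(tree.leaf_labels) + 1)
    rates, weights = model.mixture()
    cats = rng.choice(len(rates), size=n_sites, p=weights)
    Q = build_rate_matrix(model)
    spectral = SpectralRateMatrix.from_q(Q, model.frequencies)

    def sample_rows(P: np.ndarray, parent_states: np.ndarray) -> np.ndarray:
        cum = np.cumsum(P[parent_states], axis=1)
        u = rng.random(len(parent_states))
        return (u[:, None] > cum).sum(axis=1).astype(np.int8)

    root_states = rng.choice(20, size=n_sites, p=model.frequencies).astype(np.int8)
    states: dict[TreeNode, np.ndarray] = {tree.root: root_states}
    for nd in tree.preorder():
        if nd is tree.root:
            continue
        parent_states = states[nd.parent]
        t = nd.length * branch_scale
        child = np.empty(n_sites, dtype=np.int8)
        for c in range(len(rates)):
            mask = cats == c
            if not mask.any():
                continue
            if rates[c] * t == 0:
                child[mask] = parent_states[mask]
            else:
                P = spectral.probs(rates[c] * t)
                child[mask] = sample_rows(P, parent_states[mask])
        states[nd] = child

    def to_seq(codes: np.ndarray) -> str:
        return "".join(AMINO_ACIDS[i] for i in codes)

    aln = Alignment(
        labels=[lf.label for lf in tree.leaves()],
        sequences=[to_seq(states[lf]) for lf in tree.leaves()],
    )
    truth = SimulationTruth(
        seed=seed,
        ancestral_sequences={
            nd.node_id: to_seq(states[nd])
            for nd in tree.internal_nodes()
        },
        site_categories=cats,
        alpha=model.gamma_shape,
        p_inv=model.p_invariant,
        branch_scale=branch_scale,
    )
    return aln, truth


# ---------------------------------------------------------------------------
# Binding experiments


DEFAULT_COMPETITOR_SERIES_UM = np.concatenate(
    [[0.0], np.geomspace(500.0 / 3.0**10, 500.0, 11)]
)


def simulate_fp_dataset(
    kd_probe_uM: float,
    seed: int,
    kd_competitor_uM: float | None = None,
    mode: str = "competition",
    probe_nM: float = 15.0,
    protein_uM: float = 1.0,
    competitor_series_uM: np.ndarray | None = None,
    protein_series_uM: np.ndarray | None = None,
    mp_free: float = 60.0,
    mp_bound: float = 200.0,
    noise_sd_mP: float = 2.0,
    n_replicates: int = 1,
) -> tuple[list[_binding.FPExperiment], SimulationTruth]:
    """Simulate FP titrations in the study's concentration regime.

    Defaults mirror the displacement design: 15 nM probe, 0.2-2 uM protein
    (1 uM here), a 12-point competitor series, mP plateaus mapped linearly
    onto bound probe fraction, and additive Gaussian noise (2 mP).
    """
    if noise_sd_mP < 0:
        raise ValueError("noise SD must be nonnegative")
    rng = np.random.default_rng(seed)
    experiments = []
    if mode == "saturation":
        series = (
            np.geomspace(kd_probe_uM / 30, kd_probe_uM * 100, 12)
            if protein_series_uM is None
            else np.asarray(protein_series_uM, float)
        )
        probe_uM = probe_nM * 1e-3
        frac = np.array(
            [_binding.bound_fraction_single(p, probe_uM, kd_probe_uM) for p in series]
        )
        mean = mp_free + (mp_bound - mp_free) * frac
        for rep in range(n_replicates):
            noisy = mean + rng.normal(0.0, noise_sd_mP, size=mean.shape)
            experiments.append(
                _binding.FPExperiment(
                    mode="saturation",
                    probe_total_nM=probe_nM,
                    protein_totals_uM=series,
                    signal_mP=noisy,
                    replicate=rep,
                )
            )
    elif mode == "competition":
        if kd_competitor_uM is None:
            raise ValueError("competition mode needs kd_competitor_uM")
        series = (
            DEFAULT_COMPETITOR_SERIES_UM
            if competitor_series_uM is None
            else np.asarray(competitor_series_uM, float)
        )
        probe_uM = probe_nM * 1e-3
        pl = np.array(
            [
                _binding.solve_competitive_equilibrium(
                    protein_uM, probe_uM, i, kd_probe_uM, kd_competitor_uM
                ).pl
                for i in series
            ]
        )
        mean = mp_free + (mp_bound - mp_free) * pl / probe_uM
        for rep in range(n_replicates):
            noisy = mean + rng.normal(0.0, noise_sd_mP, size=mean.shape)
            experiments.append(
                _binding.FPExperiment(
                    mode="competition",
                    probe_total_nM=probe_nM,
                    protein_total_uM=protein_uM,
                    competitor_totals_uM=series,
                    signal_mP=noisy,
                    replicate=rep,
                )
            )
    else:
        raise ValueError("mode must be 'saturation' or 'competition'")
    truth = SimulationTruth(
        seed=seed,
        binding_params={
            "kd_probe_uM": kd_probe_uM,
            "kd_competitor_uM": kd_competitor_uM,
            "mp_free": mp_free,
            "mp_bound": mp_bound,
            "noise_sd_mP": noise_sd_mP,
            "protein_uM": protein_uM,
            "probe_nM": probe_nM,
        },
    )
    return experiments, truth


def simulate_itc_dataset(
    seed: int,
    n: float = 1.0,
    kd_uM: float = 0.3,
    dh_kcal: float = -8.0,
    cell_conc_uM: float = 11.0,
    syringe_conc_uM: float = 118.0,
    n_injections: int = 20,
    injection_volume_uL: float = 2.0,
    noise_sd_ucal: float = 0.0,
    temperature_K: float = 298.15,
) -> tuple[_binding.ITCExperiment, SimulationTruth]:
    """Simulate a 1:1 ITC titration at the study's cell/syringe loadings."""
    rng = np.random.default_rng(seed)
    volumes = np.full(n_injections, injection_volume_uL)
    exp = _binding.ITCExperiment(
        cell_conc_uM=cell_conc_uM,
        syringe_conc_uM=syringe_conc_uM,
        injection_volumes_uL=volumes,
        heats_ucal=np.zeros(n_injections),
        temperature_K=temperature_K,
    )
    heats = _binding.itc_injection_heats(exp, n, 1.0 / kd_uM, dh_kcal)
    heats = heats + rng.normal(0.0, noise_sd_ucal, size=heats.shape)
    exp.heats_ucal = heats
    truth = SimulationTruth(
        seed=seed,
        binding_params={
            "n": n,
            "kd_uM": kd_uM,
            "dh_kcal": dh_kcal,
            "noise_sd_ucal": noise_sd_ucal,
        },
    )
    return exp, truth


# ---------------------------------------------------------------------------
# Measured-affinity fixture


def table1_fixture() -> AffinityTable:
    """The packaged table of measured extant MDM2/p53TAD affinities."""
    return AffinityTable.packaged_fixture()
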