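"""Synthetic assay, ASR, and trait-tree generators with known ground truth.

Every pipeline input can be generated here so all stages are testable
without any external download. The defaults reproduce the study's assay
design: fluorescence measured in 3 independent replicates at 11 temperatures
on a 0-100 deg C grid at 10 deg C intervals (33 datapoints per protein),
with binding signals drawn from the asymmetric peak model plus additive
homoscedastic Gaussian noise. Each generator is a pure function of its
configuration and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import dendropy

from .consensus import AMINO_ACIDS, GAP, AncestralReconstruction
from .peak_model import PeakParams, model_fluorescence
from .profiles import FluorescenceProfile
from .trees import AnnotatedTree

DEFAULT_GRID = tuple(float(t) for t in range(0, 101, 10))


def _default_true_params() -> PeakParams:
    # a typical moderate-thermophile binding curve; amplitude 100 -> 1000 a.u.
    return PeakParams(f0=100.0, f_star=1000.0, t_star=50.0, s_l=8.0, s_r=12.0, w=5.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Design of one simulated binding assay.

    ``noise_sd`` is the additive Gaussian noise scale; when
    ``noise_relative`` is true it is interpreted as a fraction of the peak
    fluorescence ``f_star`` (fluorescence is in arbitrary units, so a
    relative scale is the natural way to state assay noise).
    """

    temperatures: Tuple[float, ...] = DEFAULT_GRID
    n_replicates: int = 3
    noise_sd: float = 0.02
    noise_relative: bool = True
    true_params: PeakParams = field(default_factory=_default_true_params)
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("temperature grid must be strictly increasing with >= 2 points")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def absolute_noise_sd(self) -> float:
        if self.noise_relative:
            return self.noise_sd * self.true_params.f_star
        return self.noise_sd


def simulate_binding_profile(
    config: SimulationConfig, protein_id: str = "sim"
) -> Tuple[FluorescenceProfile, PeakParams]:
    """Binding profile drawn from the peak model; returns (profile, truth).

    Each datapoint is ``model(t, truth) + N(0, noise_sd)``, clipped at zero
    (fluorescence intensities cannot be negative). Identical seeds give
    byte-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    t = np.asarray(config.temperatures, dtype=float)
    clean = np.asarray(model_fluorescence(t, config.true_params), dtype=float)
    noise = rng.normal(0.0, config.absolute_noise_sd, size=(config.n_replicates, t.size))
    f = np.clip(clean[None, :] + noise, 0.0, None)
    profile = FluorescenceProfile(
        protein_id=protein_id, temperatures=t, fluorescence=f, assay_kind="binding"
    )
    return profile, config.true_params


def simulate_thermofluor(
    melt_t: float,
    config: Optional[SimulationConfig] = None,
    protein_id: str = "sim",
) -> FluorescenceProfile:
    """ThermoFluor melt curve with its replicate-mean maximum at ``melt_t``.

    Shape: logistic rise of the unfolding signal up to the transition, then a
    linear decay (dye release from aggregates). Only the argmax is consumed
    downstream, so any unimodal shape with the right peak placement works.
    """
    config = config or SimulationConfig(noise_sd=0.01)
    rng = np.random.default_rng(config.seed)
    t = np.asarray(config.temperatures, dtype=float)
    # snap the peak to the nearest grid temperature
    peak_t = float(t[int(np.argmin(np.abs(t - melt_t)))])
    base, top = 100.0, 1000.0
    rise = base + (top - base) / (1.0 + np.exp(-(t - (peak_t - 10.0)) / 4.0))
    decay = np.where(t > peak_t, (t - peak_t) * (top - base) / 100.0 * 1.5, 0.0)
    clean = rise - decay
    # noise small relative to amplitude so the argmax never moves off-grid
    noise_sd = (config.noise_sd * top) if config.noise_relative else config.noise_sd
    f = np.clip(clean[None, :] + rng.normal(0.0, noise_sd, (config.n_replicates, t.size)), 0.0, None)
    return FluorescenceProfile(
        protein_id=protein_id, temperatures=t, fluorescence=f, assay_kind="stability"
    )


@dataclass(frozen=True)
class PPModel:
    """Beta-distributed posterior probabilities for simulated ASR sites.

    Correct sites draw PP ~ Beta(a_correct, b_correct) (concentrated near 1);
    erroneous sites draw from a flatter Beta shifted lower.
    """

    a_correct: float = 18.0
    b_correct: float = 2.0
    a_error: float = 4.0
    b_error: float = 3.0


def simulate_asr_set(
    true_seq: str,
    per_method_error: Sequence[float],
    pp_model: Optional[PPModel] = None,
    seed: int = 0,
    method_ids: Optional[Sequence[str]] = None,
) -> list[AncestralReconstruction]:
    """Reconstructions differing from a planted truth at independent error sites.

    Each method substitutes every non-gap site independently with its error
    probability (to a uniformly chosen different residue) and draws a
    per-site PP that is stochastically higher at correct sites.
    """
    pp_model = pp_model or PPModel()
    errors = [float(e) for e in per_method_error]
    if any(not 0.0 <= e < 0.5 for e in errors):
        raise ValueError("per-method error rates must lie in [0, 0.5)")
    true_seq = true_seq.upper()
    if method_ids is None:
        method_ids = [f"method_{i+1}" for i in range(len(errors))]
    rng = np.random.default_rng(seed)
    out = []
    for mid, err in zip(method_ids, errors):
        chars = []
        pp = np.full(len(true_seq), np.nan)
        for i, c in enumerate(true_seq):
            if c == GAP:
                chars.append(GAP)
                continue
            if rng.random() < err:
                alternatives = [a for a in AMINO_ACIDS if a != c]
                chars.append(alternatives[rng.integers(len(alternatives))])
                pp[i] = rng.beta(pp_model.a_error, pp_model.b_error)
            else:
                chars.append(c)
                pp[i] = rng.beta(pp_model.a_correct, pp_model.b_correct)
        out.append(AncestralReconstruction(mid, "".join(chars), pp))
    return out


def simulate_trait_tree(
    n_leaves: int,
    root_ogt: float = 65.5,
    step_sd: float = 8.0,
    seed: int = 0,
    noise_sd: float = 0.02,
    n_replicates: int = 3,
) -> Tuple[AnnotatedTree, Dict[str, float], Dict[str, FluorescenceProfile]]:
    """Random rooted tree with Brownian-style OGT evolution and binding assays.

    The topology is built by random sequential joins; every node (leaves and
    labeled internal nodes) receives a true OGT evolved from ``root_ogt`` by
    independent Gaussian steps of scale ``step_sd`` per branch, truncated to
    [5, 95] deg C so the peak stays on the assay grid. Each node also gets a
    simulated binding profile whose generating peak temperature equals its
    OGT. Returns (tree, true OGT per label, binding profile per label).
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    if step_sd < 0:
        raise ValueError("step_sd must be >= 0")
    rng = np.random.default_rng(seed)

    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    nodes = []
    for i in range(n_leaves):
        node = dendropy.Node()
        node.taxon = taxon_ns.new_taxon(label=f"L{i+1}")
        node.edge.length = 1.0
        nodes.append(node)
    counter = 0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        counter += 1
        parent = dendropy.Node()
        parent.label = f"N{counter}"
        parent.edge.length = 1.0
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    root.label = "root"
    tree.seed_node = root
    tree.is_rooted = True

    true_ogt: Dict[str, float] = {}
    for node in tree.preorder_node_iter():
        lab = AnnotatedTree.node_label(node)
        if node.parent_node is None:
            true_ogt[lab] = float(root_ogt)
        else:
            parent_lab = AnnotatedTree.node_label(node.parent_node)
            step = rng.normal(0.0, step_sd)
            true_ogt[lab] = float(np.clip(true_ogt[parent_lab] + step, 5.0, 95.0))

    profiles: Dict[str, FluorescenceProfile] = {}
    for lab, ogt in true_ogt.items():
        params = PeakParams(f0=100.0, f_star=1000.0, t_star=ogt, s_l=8.0, s_r=12.0, w=5.0)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        cfg = SimulationConfig(
            n_replicates=n_replicates,
            noise_sd=noise_sd,
            noise_relative=True,
            true_params=params,
            seed=sub_seed,
        )
        profiles[lab], _ = simulate_binding_profile(cfg, protein_id=lab)

    return AnnotatedTree(tree), true_ogt, profiles
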