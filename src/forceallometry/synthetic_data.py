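"""Synthetic hummingbird data with known allometric ground truth.

Generates individual-level records and tree ensembles emulating a
hovering-flight comparative data set: 25 species spanning one decade of
body weight with Brownian phylogenetic signal in log mass, lognormal
species- and individual-level biological scatter, kinematic and
morphological components whose expected log-log slopes follow configurable
among- and within-species exponents, and per-variable measurement noise.
The force coefficient is never sampled: it is implied by the force balance,
so latent (pre-noise) records satisfy W = 1/2 rho U^2 S C_V exactly and the
fitted C_V exponent carries the balance of the remaining components.

Mean wing velocity is realised through its sub-allometries with constant
stroke amplitude and second moment of area: wing length scales as half the
wing-area exponent (constant aspect ratio) and stroke frequency carries the
remainder, mirroring the observed coupling of declining frequency to
increasing wing length among species.
"""

from __future__ import annotations

import json
import random as _pyrandom
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import dendropy
import numpy as np
import pandas as pd

from .constants import STANDARD_GRAVITY
from .aeromechanics import elevation_from_air_density
from .treespace import TreeEnsemble

#: among-species force-decomposition exponents (b_rho, b_U, b_S, b_C); the
#: C_V exponent is implied by the sum-to-one force balance.
AMONG_EXPONENTS = dict(b_rho=-0.06, b_U=0.01, b_S=1.01, b_C=0.03)
#: within-species (individual-level) analogues.
WITHIN_EXPONENTS = dict(b_rho=-0.07, b_U=0.27, b_S=0.42, b_C=0.11)
#: load-factor exponents: size-invariant among species, declining within.
BURST_AMONG_EXPONENT = -0.01
BURST_WITHIN_EXPONENT = -0.24

#: per-variable measurement-error fractions (sd as a fraction of the value):
#: balance-measured mass is precise; photo-digitised areas and
#: video-digitised kinematics carry most of the error.
DEFAULT_NOISE_PROFILE = {
    "body_mass": 0.01,
    "elevation": 0.02,
    "wing_length_R": 0.02,
    "wing_area_S": 0.03,
    "r2_hat": 0.03,
    "r3_hat": 0.03,
    "hover_frequency_f": 0.01,
    "hover_amplitude_Phi": 0.03,
    "burst_frequency": 0.01,
    "burst_amplitude": 0.03,
    "burst_force": 0.05,
}

CLADE_NAMES = ["Hermits", "Mangoes", "Brilliants", "Coquettes",
               "Bees", "Emeralds", "MountainGems", "Topazes"]


@dataclass
class GeneratorConfig:
    n_species: int = 25
    individuals_per_species: Union[int, tuple[int, int]] = 10
    mass_range_decades: float = 1.0
    among_exponents: dict = field(default_factory=lambda: dict(AMONG_EXPONENTS))
    within_exponents: dict = field(default_factory=lambda: dict(WITHIN_EXPONENTS))
    burst_model: str = "constant_load_factor"
    burst_among_exponent: float = BURST_AMONG_EXPONENT
    burst_within_exponent: Optional[float] = None  # from burst_model
    # log10-scale biological scatter, species level then individual level
    species_scatter: dict = field(default_factory=lambda: dict(
        rho=0.035, R=0.02, AR=0.02, f=0.04, Phi=0.02, r2=0.01, n=0.035))
    within_scatter: dict = field(default_factory=lambda: dict(
        rho=0.010, R=0.008, AR=0.008, f=0.010, Phi=0.010, r2=0.005, n=0.010))
    mass_within_sd: float = 0.06   # log10 sd of individual mass about species
    #: None -> DEFAULT_NOISE_PROFILE; a float applies that fraction uniformly
    #: to every recorded variable; a dict overrides per variable.
    measurement_noise: Union[None, float, dict] = None
    # reference (geometric-centre) values of a typical mid-size hummingbird
    reference_weight: float = 0.05        # N (~5 g)
    reference_wing_length: float = 0.049  # m, single wing
    reference_aspect_ratio: float = 8.0
    reference_frequency: float = 45.0     # Hz
    reference_amplitude: float = 2.8      # rad, pronation-to-supination
    reference_r2: float = 0.49
    reference_r3: float = 0.55
    reference_density: float = 0.95       # kg m^-3 (~2400 m a.s.l.)
    reference_load_factor: float = 1.8
    # tree ensemble
    tree_model: str = "pure_birth"
    birth_rate: float = 1.0
    brownian_rate: float = 1.0
    n_trees: int = 100
    branch_jitter_sd: float = 0.05        # lognormal sd on edge lengths
    nni_prob: float = 0.0                 # per-ensemble-member NNI probability
    seed: int = 0
    allow_unbalanced: bool = False

    def __post_init__(self) -> None:
        if self.mass_range_decades <= 0:
            raise ValueError("mass_range_decades must be > 0")
        if self.burst_model not in ("constant_load_factor",
                                    "declining_load_factor"):
            raise ValueError(f"unknown burst model {self.burst_model!r}")
        if self.burst_within_exponent is None:
            self.burst_within_exponent = (
                BURST_WITHIN_EXPONENT
                if self.burst_model == "declining_load_factor" else 0.0)
        for name, exps in (("among", self.among_exponents),
                           ("within", self.within_exponents)):
            s = (exps["b_rho"] + 2 * exps["b_U"] + exps["b_S"] + exps["b_C"])
            if abs(s - 1.0) > 1e-9 and not self.allow_unbalanced:
                raise ValueError(
                    f"{name} exponents sum to {s}, not 1 (weight support); "
                    "set allow_unbalanced=True to override")

    def noise_fraction(self, variable: str) -> float:
        if self.measurement_noise is None:
            return DEFAULT_NOISE_PROFILE.get(variable, 0.0)
        if isinstance(self.measurement_noise, dict):
            return float(self.measurement_noise.get(variable, 0.0))
        return float(self.measurement_noise)


def make_preset(name: str, seed: int = 0, **overrides) -> GeneratorConfig:
    """Named study conditions: ``among``, ``within`` or ``layered``.

    All presets carry both the among-species and within-species exponent
    structure (the two scopes coexist in real data); they differ in the
    burst model, size-invariant load factor for ``among`` and declining
    load factor for ``within`` and ``layered``.
    """
    if name not in ("among", "within", "layered"):
        raise ValueError(f"unknown preset {name!r}")
    burst = ("constant_load_factor" if name == "among"
             else "declining_load_factor")
    return GeneratorConfig(burst_model=burst, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# trees and masses
# ---------------------------------------------------------------------------

def _pure_birth_tree(n_species: int, birth_rate: float,
                     seed: int) -> dendropy.Tree:
    from dendropy.model import birthdeath
    tree = birthdeath.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0, num_extant_tips=n_species,
        rng=_pyrandom.Random(seed))
    tree.is_rooted = True
    for i, leaf in enumerate(sorted(tree.leaf_node_iter(),
                                    key=lambda x: x.taxon.label)):
        leaf.taxon.label = f"species_{i + 1:02d}"
    return tree


def _nni(tree: dendropy.Tree, rng: np.random.Generator) -> None:
    """One random nearest-neighbour interchange on an internal edge."""
    internal = [e for e in tree.preorder_edge_iter()
                if e.head_node.child_nodes() and e.tail_node is not None
                and e.tail_node.parent_node is not None]
    if not internal:
        return
    edge = internal[int(rng.integers(len(internal)))]
    child = edge.head_node
    parent = edge.tail_node
    a = child.child_nodes()[int(rng.integers(len(child.child_nodes())))]
    sibs = [c for c in parent.child_nodes() if c is not child]
    b = sibs[int(rng.integers(len(sibs)))]
    child.remove_child(a)
    parent.remove_child(b)
    child.add_child(b)
    parent.add_child(a)


def simulate_tree_ensemble(config: GeneratorConfig,
                           ) -> tuple[dendropy.Tree, TreeEnsemble]:
    """Pure-birth generating tree plus a jittered posterior-like ensemble."""
    if config.n_species < 3:
        raise ValueError("need at least 3 species")
    base = _pure_birth_tree(config.n_species, config.birth_rate, config.seed)
    rng = np.random.default_rng(config.seed)
    members = []
    for _ in range(config.n_trees):
        t = base.clone(depth=1)
        if config.branch_jitter_sd > 0:
            for e in t.preorder_edge_iter():
                if e.length is not None:
                    e.length = float(
                        e.length * rng.lognormal(0.0, config.branch_jitter_sd))
        if config.nni_prob > 0 and rng.uniform() < config.nni_prob:
            _nni(t, rng)
        members.append(t)
    return base, TreeEnsemble(members, source="synthetic")


def simulate_species_masses(tree: dendropy.Tree, config: GeneratorConfig,
                            ) -> dict[str, float]:
    """Brownian log10 body mass on the tree, rescaled to the target span."""
    rng = np.random.default_rng(config.seed + 1)
    value: dict[int, float] = {}
    tips: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            value[id(node)] = 0.0
        else:
            el = node.edge.length or 0.0
            step = (rng.normal(0.0, np.sqrt(config.brownian_rate * el))
                    if config.brownian_rate > 0 and el > 0 else 0.0)
            value[id(node)] = value[id(node.parent_node)] + step
        if node.is_leaf():
            tips[node.taxon.label] = value[id(node)]
    vals = np.array(list(tips.values()))
    centre = np.log10(config.reference_weight / STANDARD_GRAVITY)
    span = vals.max() - vals.min()
    if span > 0:
        scaled = ((vals - vals.min()) / span - 0.5) * config.mass_range_decades
    else:
        scaled = np.zeros_like(vals)
    return {k: centre + s for k, s in zip(tips, scaled)}


def _assign_clades(tree: dendropy.Tree, max_size: int) -> dict[str, str]:
    """Partition tips into phylogenetically coherent named groups."""
    groups: list[list[str]] = []

    def split(node):
        tips = [lf.taxon.label for lf in node.leaf_iter()]
        if len(tips) <= max_size or node.is_leaf():
            groups.append(tips)
            return
        for c in node.child_nodes():
            split(c)

    split(tree.seed_node)
    out = {}
    for gi, tips in enumerate(groups):
        name = CLADE_NAMES[gi % len(CLADE_NAMES)]
        for t in tips:
            out[t] = name
    return out


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    records: pd.DataFrame
    trees: TreeEnsemble
    generating_tree: dendropy.Tree
    truth: dict


def simulate_records(config: Optional[GeneratorConfig] = None,
                     ) -> SyntheticDataset:
    """Generate a full synthetic data set under ``config``.

    Latent (pre-measurement-noise) records satisfy the force balance
    exactly at both the species and the individual level; measurement noise
    is then applied independently to every recorded variable, so derived
    force coefficients absorb the injected errors just as in real data.
    """
    cfg = config or GeneratorConfig()
    base_tree, ensemble = simulate_tree_ensemble(cfg)
    log_masses = simulate_species_masses(base_tree, cfg)
    clades = _assign_clades(base_tree, max(3, int(np.ceil(cfg.n_species / 4))))
    rng = np.random.default_rng(cfg.seed + 2)

    am = cfg.among_exponents
    wi = cfg.within_exponents
    ss = cfg.species_scatter
    ws = cfg.within_scatter
    g = STANDARD_GRAVITY
    w0 = cfg.reference_weight

    rows = []
    for sp in sorted(log_masses):
        log_w_sp = log_masses[sp] + np.log10(g)
        dw = log_w_sp - np.log10(w0)

        rho_sp = cfg.reference_density * 10 ** (
            am["b_rho"] * dw + rng.normal(0, ss["rho"]))
        R_sp = cfg.reference_wing_length * 10 ** (
            0.5 * am["b_S"] * dw + rng.normal(0, ss["R"]))
        AR_sp = cfg.reference_aspect_ratio * 10 ** rng.normal(0, ss["AR"])
        f_sp = cfg.reference_frequency * 10 ** (
            (am["b_U"] - 0.5 * am["b_S"]) * dw + rng.normal(0, ss["f"]))
        phi_sp = cfg.reference_amplitude * 10 ** rng.normal(0, ss["Phi"])
        r2_sp = cfg.reference_r2 * 10 ** rng.normal(0, ss["r2"])
        n_sp = cfg.reference_load_factor * 10 ** (
            cfg.burst_among_exponent * dw + rng.normal(0, ss["n"]))

        if isinstance(cfg.individuals_per_species, tuple):
            lo, hi = cfg.individuals_per_species
            n_ind = int(rng.integers(lo, hi + 1))
        else:
            n_ind = int(cfg.individuals_per_species)

        for j in range(n_ind):
            delta = rng.normal(0, cfg.mass_within_sd)
            mass = 10 ** (log_masses[sp] + delta)
            rho = rho_sp * 10 ** (wi["b_rho"] * delta + rng.normal(0, ws["rho"]))
            rho = float(np.clip(rho, 0.72, 1.21))
            R = R_sp * 10 ** (0.5 * wi["b_S"] * delta + rng.normal(0, ws["R"]))
            AR = AR_sp * 10 ** rng.normal(0, ws["AR"])
            f = f_sp * 10 ** ((wi["b_U"] - 0.5 * wi["b_S"]) * delta
                              + rng.normal(0, ws["f"]))
            phi = min(phi_sp * 10 ** rng.normal(0, ws["Phi"]), 3.3)
            r2 = float(np.clip(r2_sp * 10 ** rng.normal(0, ws["r2"]),
                               0.30, 0.70))
            n_load = max(n_sp * 10 ** (cfg.burst_within_exponent * delta
                                       + rng.normal(0, ws["n"])), 1.05)
            elevation = elevation_from_air_density(rho)
            burst_f = f * 1.08
            burst_phi = min(phi * 1.12, 3.3)
            burst_force = n_load * mass * g

            def noisy(value, variable):
                frac = cfg.noise_fraction(variable)
                if frac <= 0:
                    return value
                factor = max(1.0 + frac * rng.standard_normal(), 0.05)
                return value * factor

            mass_m = noisy(mass, "body_mass")
            R_m = noisy(R, "wing_length_R")
            S_m = noisy(4.0 * R * R / AR, "wing_area_S")
            elev_m = float(np.clip(noisy(elevation, "elevation"), 0.0, 10999.0))
            rows.append(dict(
                id=f"{sp}_ind{j + 1:02d}",
                species=sp,
                clade=clades[sp],
                collector="synthetic",
                elevation=elev_m,
                body_mass=mass_m,
                weight=mass_m * g,
                wing_area_S=S_m,
                wing_length_R=R_m,
                r2_hat=float(np.clip(noisy(r2, "r2_hat"), 0.05, 0.95)),
                r3_hat=float(np.clip(
                    noisy(cfg.reference_r3, "r3_hat"), 0.05, 0.95)),
                aspect_ratio=4.0 * R_m * R_m / S_m,
                hover_frequency_f=noisy(f, "hover_frequency_f"),
                hover_amplitude_Phi=noisy(phi, "hover_amplitude_Phi"),
                burst_frequency=noisy(burst_f, "burst_frequency"),
                burst_amplitude=noisy(burst_phi, "burst_amplitude"),
                burst_force=noisy(burst_force, "burst_force"),
            ))

    records = pd.DataFrame(rows)
    truth = dict(
        among_exponents=dict(am), within_exponents=dict(wi),
        burst_among_exponent=cfg.burst_among_exponent,
        burst_within_exponent=cfg.burst_within_exponent,
        burst_model=cfg.burst_model,
        n_species=cfg.n_species,
        individuals_per_species=cfg.individuals_per_species,
        mass_range_decades=cfg.mass_range_decades,
        seed=cfg.seed,
    )
    return SyntheticDataset(records=records, trees=ensemble,
                            generating_tree=base_tree, truth=truth)


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Emit records.csv, trees.nex and truth.json into ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.records.to_csv(out / "records.csv", index=False)
    tl = dendropy.TreeList(dataset.trees.trees,
                           taxon_namespace=dataset.trees.trees[0].taxon_namespace)
    tl.write(path=str(out / "trees.nex"), schema="nexus")
    with open(out / "truth.json", "w") as fh:
        json.dump(dataset.truth, fh, indent=2)
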