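"""Taxon-structured synthetic collagen-like PMFs with known ground truth.

A random ultrametric taxonomy is drawn, a root set of peptide masses (with
peptide-like mass defects) evolves along its branches by residue
substitutions whose mass shifts come from the amino-acid mass-difference
alphabet, and per-individual spectra are emitted with detection dropout,
log-normal intensity noise, uniform noise peaks and fixed matrix peaks.
Companion aligned sequences share the same mutation events, so sequence
divergence and fingerprint divergence are coupled by construction.

Everything is reproducible from ``(config, seed)``: the taxonomy, evolution
and spectrum stages each derive an independent stream from the seed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace

import numpy as np

from .feature_matrix import PEPTIDE_DEFECT_SLOPE
from .seq_divergence import CHAIN_RATES
from .spectra_io import Spectrum

#: Monoisotopic residue masses (Da) of the 20 proteinogenic amino acids.
RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

#: Minimum |mass shift| considered visible at PMF precision (drops Leu/Ile).
MIN_VISIBLE_SHIFT = 0.02

#: Residues allowed at Xaa/Yaa positions of the Gly-Xaa-Yaa repeat.
_XAA = "APSTVLIKRDEQNFYHMW"

#: Residues per peptide segment in the companion alignment.
SEGMENT_LENGTH = 15

PRESETS = {
    "fish": {"divergence_scale": 2.0, "detection_prob": 0.7},
    "mammal": {"divergence_scale": 1.0, "detection_prob": 0.9},
}


def mass_shift_alphabet(min_abs: float = MIN_VISIBLE_SHIFT) -> np.ndarray:
    """Signed pairwise residue mass differences above the visibility floor."""
    masses = np.array(list(RESIDUE_MASS.values()))
    diffs = (masses[:, None] - masses[None, :]).ravel()
    return np.unique(diffs[np.abs(diffs) >= min_abs])


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic PMF generator (seed is mandatory)."""

    seed: int
    n_families: int = 6
    depth_mya: float = 150.0
    n_individuals: int = 6
    n_peptides: int = 60
    divergence_scale: float = 1.0
    detection_prob: float = 0.9
    intensity_cv: float = 0.3
    n_noise_peaks: int = 5
    matrix_peak_mz: tuple[float, ...] = (1060.1,)
    mz_range: tuple[float, float] = (900.0, 3500.0)
    per_peptide_rate_per_mya: float = 0.001

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_families < 2:
            raise ValueError("n_families must be >= 2")
        if self.n_peptides < 1:
            raise ValueError("n_peptides must be >= 1")
        if not 0 < self.detection_prob <= 1:
            raise ValueError("detection_prob must lie in (0, 1]")
        if self.intensity_cv < 0:
            raise ValueError("intensity_cv must be >= 0")
        if self.depth_mya <= 0 or self.divergence_scale < 0:
            raise ValueError("depth_mya > 0 and divergence_scale >= 0 required")

    def with_preset(self, preset: str) -> "SimulationConfig":
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from "
                             f"{sorted(PRESETS)}")
        return replace(self, **PRESETS[preset])


@dataclass
class _Node:
    height: float
    name: str | None = None
    children: list = field(default_factory=list)
    branch_id: int = -1  # id of the branch leading INTO this node

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        return [x for ch in self.children for x in ch.leaves()]


@dataclass
class Taxonomy:
    """Random ultrametric tree over family-level leaves."""

    root: _Node
    leaf_names: list[str]
    _pair_ed: dict[tuple[str, str], float]

    def ed(self, a: str, b: str) -> float:
        """Median-style divergence time (Mya) between two leaves."""
        if a == b:
            return 0.0
        return self._pair_ed[tuple(sorted((a, b)))]

    def pairwise_ed(self) -> dict[tuple[str, str], float]:
        return dict(self._pair_ed)

    def branches(self) -> list[tuple[_Node, _Node, float]]:
        """(parent, child, branch length) in pre-order."""
        out = []

        def walk(node):
            for ch in node.children:
                out.append((node, ch, node.height - ch.height))
                walk(ch)

        walk(self.root)
        return out

    def leaf_branch_paths(self) -> dict[str, frozenset[int]]:
        """For each leaf, the set of branch ids on its root-to-leaf path."""
        paths: dict[str, frozenset[int]] = {}

        def walk(node, acc):
            if node.is_leaf:
                paths[node.name] = frozenset(acc)
                return
            for ch in node.children:
                walk(ch, acc | {ch.branch_id})

        walk(self.root, frozenset())
        return paths

    def newick(self) -> str:
        def fmt(node, parent_height):
            bl = parent_height - node.height
            if node.is_leaf:
                return f"{node.name}:{bl:.6f}"
            inner = ",".join(fmt(ch, node.height) for ch in node.children)
            return f"({inner}):{bl:.6f}"

        inner = ",".join(fmt(ch, self.root.height) for ch in self.root.children)
        return f"({inner});"


def simulate_taxonomy(n_families: int, depth_mya: float,
                      seed: int) -> Taxonomy:
    """Random bifurcating ultrametric tree with root depth ``depth_mya``.

    Built by coalescent-style merging: lineages start at the present and pairs
    merge at increasing times, the last merge fixed at ``depth_mya``.
    """
    if n_families < 2:
        raise ValueError("n_families must be >= 2")
    rng = np.random.default_rng([1, seed])
    names = [f"Fam{i + 1:02d}" for i in range(n_families)]
    lineages = [_Node(height=0.0, name=nm) for nm in names]
    if n_families == 2:
        times = np.array([depth_mya])
    else:
        times = np.sort(rng.uniform(0.0, depth_mya, size=n_families - 2))
        times = np.append(times, depth_mya)
    pair_ed: dict[tuple[str, str], float] = {}
    for t in times:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        right = lineages.pop(j)
        left = lineages.pop(i)
        for a in left.leaves():
            for b in right.leaves():
                pair_ed[tuple(sorted((a, b)))] = float(t)
        lineages.append(_Node(height=float(t), children=[left, right]))
    root = lineages[0]
    for bid, (_, child, _) in enumerate(
            Taxonomy(root, names, {}).branches()):
        child.branch_id = bid
    return Taxonomy(root=root, leaf_names=names, _pair_ed=pair_ed)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    leaf_masses: dict[str, np.ndarray]
    sequences: dict[str, str]
    marker_peaks: dict[str, list[float]]
    pair_substitutions: dict[tuple[str, str], int]
    pair_ed: dict[tuple[str, str], float]
    chains: list[str]
    base_intensity: np.ndarray
    events: list[tuple[int, int, int, str, str, float]]
    root_masses: np.ndarray

    def to_json(self) -> str:
        return json.dumps(
            {
                "leaf_masses": {k: list(v) for k, v in self.leaf_masses.items()},
                "sequences": self.sequences,
                "marker_peaks": self.marker_peaks,
                "pair_substitutions": {
                    f"{a}|{b}": v for (a, b), v in self.pair_substitutions.items()
                },
                "pair_ed": {f"{a}|{b}": v for (a, b), v in self.pair_ed.items()},
                "chains": self.chains,
            },
            indent=2,
        )


def _root_state(config: SimulationConfig, rng: np.random.Generator):
    lo, hi = config.mz_range
    nominal = rng.uniform(lo, hi - 1.0, size=config.n_peptides)
    base = np.floor(nominal)
    jitter = rng.normal(0.0, 0.03, size=config.n_peptides)
    frac = np.mod(PEPTIDE_DEFECT_SLOPE * base + jitter, 1.0)
    masses = base + frac
    chains = [
        sorted(CHAIN_RATES)[i % len(CHAIN_RATES)]
        for i in range(config.n_peptides)
    ]
    seq = []
    for i in range(config.n_peptides * SEGMENT_LENGTH):
        seq.append("G" if i % 3 == 0 else rng.choice(list(_XAA)))
    base_intensity = rng.uniform(10.0, 100.0, size=config.n_peptides)
    return masses, chains, "".join(seq), base_intensity


def _mutate(seq: list[str], masses: np.ndarray, peptide: int,
            rng: np.random.Generator) -> tuple[int, str, str, float]:
    start = peptide * SEGMENT_LENGTH
    mutable = [start + k for k in range(SEGMENT_LENGTH) if (start + k) % 3 != 0]
    pos = int(rng.choice(mutable))
    old = seq[pos]
    candidates = [
        r for r in RESIDUE_MASS
        if r != old and abs(RESIDUE_MASS[r] - RESIDUE_MASS[old])
        >= MIN_VISIBLE_SHIFT
    ]
    new = str(rng.choice(candidates))
    delta = RESIDUE_MASS[new] - RESIDUE_MASS[old]
    seq[pos] = new
    masses[peptide] += delta
    return pos, old, new, delta


def _evolve(tree: Taxonomy, config: SimulationConfig) -> GroundTruth:
    rng = np.random.default_rng([2, config.seed])
    root_masses, chains, root_seq, base_intensity = _root_state(config, rng)
    rates = np.array([CHAIN_RATES[c] for c in chains])

    leaf_masses: dict[str, np.ndarray] = {}
    sequences: dict[str, str] = {}
    events: list[tuple[int, int, int, str, str, float]] = []
    branch_events: dict[int, int] = {}

    def walk(node, masses, seq):
        if node.is_leaf:
            leaf_masses[node.name] = masses
            sequences[node.name] = "".join(seq)
            return
        for child in node.children:
            length = node.height - child.height
            m = masses.copy()
            s = list(seq)
            lam = rates * config.divergence_scale * \
                config.per_peptide_rate_per_mya * length
            n_events = rng.poisson(lam)
            count = 0
            for p in np.flatnonzero(n_events):
                for _ in range(int(n_events[p])):
                    pos, old, new, delta = _mutate(s, m, int(p), rng)
                    events.append((child.branch_id, int(p), pos, old, new,
                                   float(delta)))
                    count += 1
            branch_events[child.branch_id] = count
            walk(child, m, s)

    walk(tree.root, root_masses.copy(), list(root_seq))

    paths = tree.leaf_branch_paths()
    pair_subs = {}
    for a, b in itertools.combinations(sorted(leaf_masses), 2):
        on_path = paths[a] ^ paths[b]
        pair_subs[(a, b)] = int(sum(branch_events.get(x, 0) for x in on_path))

    marker_peaks = _unique_masses(leaf_masses)
    return GroundTruth(
        leaf_masses=leaf_masses, sequences=sequences,
        marker_peaks=marker_peaks, pair_substitutions=pair_subs,
        pair_ed=tree.pairwise_ed(), chains=chains,
        base_intensity=base_intensity, events=events,
        root_masses=root_masses,
    )


def _unique_masses(leaf_masses: dict[str, np.ndarray],
                   separation: float = 0.6) -> dict[str, list[float]]:
    """Masses found in exactly one leaf, >= separation from all others."""
    out: dict[str, list[float]] = {}
    for leaf, masses in leaf_masses.items():
        others = np.concatenate(
            [v for k, v in leaf_masses.items() if k != leaf]
        )
        unique = [
            float(m) for m in masses
            if np.min(np.abs(others - m)) >= separation
        ]
        out[leaf] = sorted(unique)
    return out


def evolve_peptides(tree: Taxonomy, config: SimulationConfig
                    ) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Evolve the root peptide set along the tree; returns leaf mass sets."""
    truth = _evolve(tree, config)
    return truth.leaf_masses, truth


def generate_alignments(tree: Taxonomy, config: SimulationConfig
                        ) -> dict[str, str]:
    """Aligned leaf sequences sharing the mutation events of the peptides.

    Deterministically coupled to :func:`evolve_peptides` through the seed, so
    sequence count differences track the recorded substitution counts.
    """
    return _evolve(tree, config).sequences


def generate_spectra(leaf_masses: dict[str, np.ndarray],
                     config: SimulationConfig,
                     base_intensity: np.ndarray | None = None
                     ) -> list[Spectrum]:
    """Per-individual spectra with dropout, intensity noise and contaminants."""
    rng = np.random.default_rng([3, config.seed])
    if base_intensity is None:
        base_intensity = np.full(config.n_peptides, 50.0)
    cv = config.intensity_cv
    sigma = float(np.sqrt(np.log1p(cv ** 2))) if cv > 0 else 0.0
    lo, hi = config.mz_range
    spectra = []
    for leaf in sorted(leaf_masses):
        masses = leaf_masses[leaf]
        for i in range(config.n_individuals):
            detected = rng.random(len(masses)) < config.detection_prob
            if sigma > 0:
                factors = rng.lognormal(-sigma ** 2 / 2.0, sigma, len(masses))
            else:
                factors = np.ones(len(masses))
            mz = list(masses[detected])
            inten = list((base_intensity * factors)[detected])
            for _ in range(config.n_noise_peaks):
                mz.append(float(rng.uniform(lo, hi)))
                inten.append(float(rng.uniform(1.0, 15.0)))
            for m in config.matrix_peak_mz:
                mz.append(float(m))
                inten.append(float(rng.uniform(20.0, 80.0)))
            mz = np.asarray(mz)
            inten = np.asarray(inten)
            # exact m/z collisions are vanishingly rare; merge them anyway
            mz, inverse = np.unique(mz, return_inverse=True)
            merged = np.zeros_like(mz)
            np.add.at(merged, inverse, inten)
            spectra.append(
                Spectrum(
                    sample_id=f"{leaf}_s{i + 1:02d}", mz=mz, intensity=merged,
                    family=leaf, genus=f"{leaf}_gen", dataset="synthetic",
                )
            )
    return spectra


@dataclass
class SimulationResult:
    config: SimulationConfig
    tree: Taxonomy
    truth: GroundTruth
    spectra: list[Spectrum]


def simulate(config: SimulationConfig, preset: str | None = None
             ) -> SimulationResult:
    """Full generator run: taxonomy -> peptide evolution -> spectra."""
    if preset is not None:
        config = config.with_preset(preset)
    tree = simulate_taxonomy(config.n_families, config.depth_mya, config.seed)
    truth = _evolve(tree, config)
    spectra = generate_spectra(truth.leaf_masses, config,
                               truth.base_intensity)
    return SimulationResult(config=config, tree=tree, truth=truth,
                            spectra=spectra)
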