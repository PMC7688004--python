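"""Synthetic chains, complexes, and affinities with known ground truth.

Two affinity scenarios are provided:

``linear_in_features``
    The binding free energy is an exact linear function of the unit-normed
    complex descriptor (default: amino-acid composition) plus Gaussian noise:
    ``y = w* . psi(c)/||psi(c)|| + b* + eps``.  Chains are drawn from a small
    shared pool (proteins recur across complexes, as receptors and ligands do
    in affinity benchmarks); the pool also keeps the feature matrix rank well
    below the cross-validation fold size, so the linear truth is identifiable
    in every leave-one-out fold and noise-free recovery is exact.

``similarity_smooth``
    A set of anchor complexes with affinities spread over the plausible range;
    each generated complex is a point-mutated copy of an anchor and its
    affinity drifts away from the anchor's in proportion to the mutation
    fraction (``y = y_anchor + decay * rho + eps``).  Affinity is therefore a
    smooth function of sequence similarity — the regime in which a
    nearest-homolog predictor is meaningful.

Generated free energies are clipped to a plausible range (default [-19, -4]
kcal/mol, mirroring experimental affinity benchmarks).  Identical spec and
seed give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .alphabet import AMINO_ACIDS
from .complexes import ComplexFeaturizer
from .io import (
    ComplexDataset,
    ProteinChain,
    ProteinComplex,
    write_complex_table,
    write_fasta,
)

#: Approximate natural amino-acid background frequencies (order ACDEFGHIKLMNPQRSTVWY).
NATURAL_FREQUENCIES = np.array(
    [
        0.0825, 0.0137, 0.0546, 0.0672, 0.0386, 0.0707, 0.0228, 0.0591, 0.0580,
        0.0965, 0.0241, 0.0406, 0.0474, 0.0394, 0.0553, 0.0665, 0.0536, 0.0687,
        0.0110, 0.0292,
    ]
)
NATURAL_FREQUENCIES = NATURAL_FREQUENCIES / NATURAL_FREQUENCIES.sum()

AFFINITY_MODELS = ("linear_in_features", "similarity_smooth")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_complexes: int = 40
    chain_length: tuple[int, int] = (50, 80)
    chains_per_side: tuple[int, int] = (1, 2)
    affinity_model: str = "linear_in_features"
    descriptor: str = "aac"          # linear scenario: descriptor the truth is linear in
    signal_sd: float = 1.5           # kcal/mol spread of the linear signal
    intercept: float = -11.0         # kcal/mol baseline affinity
    chain_pool_size: int = 4         # linear scenario: shared chain pool
    n_anchors: int = 5               # similarity scenario: anchor complexes
    decay: float = 3.0               # kcal/mol affinity drift per unit mutation fraction
    mutation_rate_max: float = 0.3   # similarity scenario: max point-substitution rate
    noise_sd: float = 0.0            # kcal/mol Gaussian label noise
    clip_range: tuple[float, float] = (-19.0, -4.0)
    residue_model: str = "uniform"   # 'uniform' or 'natural'
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_complexes < 1:
            raise ValueError("n_complexes must be >= 1")
        if self.chain_length[0] < 1 or self.chain_length[0] > self.chain_length[1]:
            raise ValueError(f"invalid chain_length range {self.chain_length}")
        if self.chains_per_side[0] < 1 or self.chains_per_side[0] > self.chains_per_side[1]:
            raise ValueError(f"invalid chains_per_side range {self.chains_per_side}")
        if self.affinity_model not in AFFINITY_MODELS:
            raise ValueError(
                f"unknown affinity model {self.affinity_model!r}; valid: {AFFINITY_MODELS}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.chain_pool_size < 2:
            raise ValueError("chain_pool_size must be >= 2")
        if not 0 < self.mutation_rate_max <= 1:
            raise ValueError("mutation_rate_max must be in (0, 1]")
        if self.clip_range[0] >= self.clip_range[1]:
            raise ValueError(f"invalid clip_range {self.clip_range}")


def _random_sequence(rng: np.random.Generator, length: int, residue_model: str) -> str:
    if residue_model == "uniform":
        idx = rng.integers(0, 20, size=length)
    elif residue_model == "natural":
        idx = rng.choice(20, size=length, p=NATURAL_FREQUENCIES)
    else:
        raise ValueError(f"unknown residue model {residue_model!r}")
    return "".join(AMINO_ACIDS[i] for i in idx)


def _random_chain(rng, spec: SyntheticSpec, chain_id: str) -> ProteinChain:
    length = int(rng.integers(spec.chain_length[0], spec.chain_length[1] + 1))
    return ProteinChain(id=chain_id, sequence=_random_sequence(rng, length, spec.residue_model))


def mutate_complex(
    c: ProteinComplex,
    point_sub_rate: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    force_change: bool = False,
    id_suffix: str = "_mut",
) -> ProteinComplex:
    """Point-substitute each residue independently at the given rate.

    With the default uniform replacement a substituted position keeps its
    original residue with probability 1/20, so the expected changed fraction
    is ``rate * 19/20``; ``force_change=True`` samples replacements from the
    19 other residues.  Position and replacement draws are made for every
    residue regardless of rate, so runs with the same seed and different rates
    are coupled (lower-rate mutation sets are nested in higher-rate ones).
    """
    if not 0.0 <= point_sub_rate <= 1.0:
        raise ValueError("point_sub_rate must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)

    def mutate_chain(ch: ProteinChain) -> ProteinChain:
        residues = list(ch.sequence)
        hit = rng.random(len(residues)) < point_sub_rate
        replacements = rng.integers(0, 20 if not force_change else 19, size=len(residues))
        for i, flag in enumerate(hit):
            if not flag:
                continue
            if force_change:
                pool = [aa for aa in AMINO_ACIDS if aa != residues[i]]
                residues[i] = pool[replacements[i]]
            else:
                residues[i] = AMINO_ACIDS[replacements[i]]
        return ProteinChain(id=ch.id + id_suffix, sequence="".join(residues))

    return ProteinComplex(
        id=c.id + id_suffix,
        ligand=tuple(mutate_chain(ch) for ch in c.ligand),
        receptor=tuple(mutate_chain(ch) for ch in c.receptor),
        delta_g=c.delta_g,
        kd=c.kd,
    )


def _generate_linear(spec: SyntheticSpec, rng) -> tuple[ComplexDataset, dict]:
    pool = [
        _random_chain(rng, spec, f"P{i + 1:02d}") for i in range(spec.chain_pool_size)
    ]
    complexes = []
    for i in range(spec.n_complexes):
        n_l = int(rng.integers(spec.chains_per_side[0], spec.chains_per_side[1] + 1))
        n_r = int(rng.integers(spec.chains_per_side[0], spec.chains_per_side[1] + 1))
        ligand = tuple(pool[j] for j in rng.integers(0, len(pool), n_l))
        receptor = tuple(pool[j] for j in rng.integers(0, len(pool), n_r))
        complexes.append(
            ProteinComplex(id=f"C{i + 1:03d}", ligand=ligand, receptor=receptor)
        )

    X = ComplexFeaturizer(descriptor=spec.descriptor).fit().transform(complexes)
    Xn = X / np.linalg.norm(X, axis=1, keepdims=True)
    w_raw = rng.normal(size=X.shape[1])
    raw_signal = Xn @ w_raw
    spread = float(np.std(raw_signal))
    factor = spec.signal_sd / spread if spread > 0 else 1.0
    w_star = w_raw * factor
    # centre the signal so the intercept is the dataset-mean affinity
    b_star = spec.intercept - float(np.mean(raw_signal)) * factor
    noise = rng.normal(0.0, spec.noise_sd, size=spec.n_complexes)
    y_exact = Xn @ w_star + b_star
    y = np.clip(y_exact + noise, *spec.clip_range)
    labelled = [
        ProteinComplex(
            id=c.id, ligand=c.ligand, receptor=c.receptor, delta_g=float(y[i])
        )
        for i, c in enumerate(complexes)
    ]
    truth = {
        "affinity_model": "linear_in_features",
        "descriptor": spec.descriptor,
        "feature_map": "unit_norm",
        "w_star": w_star.tolist(),
        "intercept": b_star,
        "noise": noise.tolist(),
        "y_before_noise": y_exact.tolist(),
        "clipped": (np.abs(y - (y_exact + noise)) > 0).tolist(),
    }
    return ComplexDataset(labelled, provenance="synthetic linear_in_features"), truth


def _generate_similarity(spec: SyntheticSpec, rng) -> tuple[ComplexDataset, dict]:
    lo, hi = spec.clip_range
    margin = 0.1 * (hi - lo)
    anchor_y = np.linspace(lo + margin, hi - margin - spec.decay * spec.mutation_rate_max,
                           spec.n_anchors)
    anchors = []
    for a in range(spec.n_anchors):
        n_l = int(rng.integers(spec.chains_per_side[0], spec.chains_per_side[1] + 1))
        n_r = int(rng.integers(spec.chains_per_side[0], spec.chains_per_side[1] + 1))
        anchors.append(
            ProteinComplex(
                id=f"A{a + 1:02d}",
                ligand=tuple(
                    _random_chain(rng, spec, f"A{a + 1:02d}_L{k + 1}") for k in range(n_l)
                ),
                receptor=tuple(
                    _random_chain(rng, spec, f"A{a + 1:02d}_R{k + 1}") for k in range(n_r)
                ),
            )
        )
    complexes = []
    records = []
    noise = rng.normal(0.0, spec.noise_sd, size=spec.n_complexes)
    for i in range(spec.n_complexes):
        a = int(rng.integers(0, spec.n_anchors))
        rho = float(rng.random()) * spec.mutation_rate_max
        mutated = mutate_complex(anchors[a], rho, rng=rng, id_suffix=f"_c{i + 1:03d}")
        y_exact = float(anchor_y[a] + spec.decay * rho)
        y = float(np.clip(y_exact + noise[i], lo, hi))
        complexes.append(
            ProteinComplex(
                id=f"C{i + 1:03d}",
                ligand=mutated.ligand,
                receptor=mutated.receptor,
                delta_g=y,
            )
        )
        records.append({"anchor": anchors[a].id, "rho": rho, "y_before_noise": y_exact})
    truth = {
        "affinity_model": "similarity_smooth",
        "anchor_affinities": anchor_y.tolist(),
        "decay": spec.decay,
        "noise": noise.tolist(),
        "complex_records": records,
    }
    return ComplexDataset(complexes, provenance="synthetic similarity_smooth"), truth


def generate(spec: SyntheticSpec) -> tuple[ComplexDataset, dict]:
    """Generate a dataset and its ground-truth record from a spec."""
    rng = np.random.default_rng(spec.seed)
    if spec.affinity_model == "linear_in_features":
        return _generate_linear(spec, rng)
    return _generate_similarity(spec, rng)


def write_run(
    dataset: ComplexDataset, truth: dict, spec: SyntheticSpec, outdir: str | Path
) -> dict[str, Path]:
    """Write FASTA + complex table + JSON manifest to a run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "chains.fasta",
        "complexes": outdir / "complexes.csv",
        "manifest": outdir / "manifest.json",
    }
    write_fasta(dataset.unique_chains(), paths["fasta"])
    write_complex_table(dataset, paths["complexes"])
    manifest = {"spec": asdict(spec), "ground_truth": truth}
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
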