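"""Synthetic centroided imaging-MS data with planted ground truth.

The generator emulates the features of real centroided data the annotation
engine depends on: planted ions with T isotopic peaks at theoretical m/z
values jittered within a ppm tolerance, spatially structured intensity
images (smooth random blobs, so planted ions are spatially informative),
uniform-random noise peaks that decoy ions occasionally match (required for
non-degenerate FDR curves), and optional profile-mode peak shoulders (dense
sub-tolerance satellite peaks) emulating mistakenly submitted
non-centroided data.

It does not emulate instrument-specific peak shapes, mass-resolution decay,
or real tissue morphology; passing tests demonstrate correctness of the
pipeline's computations, not performance on real tissue data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io import CentroidedDataset, CentroidedSpectrum, MoleculeRecord
from .isotopes import pattern_for
from .scoring import FEATURE_NAMES

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "toy_database",
    "generate_dataset",
    "generate_corpus",
    "generate_feature_corpus",
    "simulate_exchangeable_ranking",
]

_SUBCLASSES = (
    ("Amino acids, peptides, and analogues", "Organic acids and derivatives"),
    ("Fatty acids and conjugates", "Lipids and lipid-like molecules"),
    ("Glycerophosphocholines", "Lipids and lipid-like molecules"),
    ("Carbohydrates and carbohydrate conjugates", "Organic oxygen compounds"),
    ("Triradylcglycerols", "Lipids and lipid-like molecules"),
)


def toy_database(n: int = 30, seed: int = 7) -> list[MoleculeRecord]:
    """A small synthetic molecular database with class labels.

    Formulas are random CHNO compositions in the metabolite mass range;
    subclass/parent-class labels cycle through a handful of realistic
    names so enrichment analysis has structure to find.
    """
    rng = np.random.default_rng(seed)
    records: list[MoleculeRecord] = []
    seen: set[str] = set()
    while len(records) < n:
        c = int(rng.integers(5, 31))
        h = int(rng.integers(max(4, c // 2), 2 * c + 3))
        o = int(rng.integers(1, 11))
        nn = int(rng.integers(0, 5))
        formula = f"C{c}H{h}" + (f"N{nn}" if nn else "") + f"O{o}"
        if formula in seen:
            continue
        seen.add(formula)
        sub, parent = _SUBCLASSES[len(records) % len(_SUBCLASSES)]
        records.append(
            MoleculeRecord(
                formula=formula,
                name=f"M{len(records):03d}",
                subclass=sub,
                parent_class=parent,
            )
        )
    return records


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a small but realistic acquisition: a 32x32 pixel
    grid, 10 planted molecules with T=4 isotopic peaks, 0.5 ppm mass
    jitter (well inside the 3 ppm matching tolerance), 30 noise peaks per
    pixel over a 100-1000 m/z range, and a signal-to-noise ratio of 10.
    """

    seed: int
    grid_shape: tuple[int, int] = (32, 32)
    n_molecules: int = 10
    database: list[MoleculeRecord] | None = None
    adducts: tuple[str, ...] = ("+H",)
    polarity: str = "positive"
    T: int = 4
    jitter_ppm: float = 0.5
    noise_peaks_per_pixel: float = 30.0
    amplitude: float = 1000.0
    snr: float = 10.0
    mz_range: tuple[float, float] = (100.0, 1000.0)
    spatial_pattern: str = "blob"  # blob | region | uniform
    profile_mode_shoulders: bool = False
    analyzer: str = "Orbitrap"
    source: str = "MALDI"
    metadata: dict = field(default_factory=dict)


@dataclass
class GroundTruth:
    planted: list[tuple[str, str]]  # (formula, adduct)
    snr: dict[tuple[str, str], float]
    masks: dict[tuple[str, str], np.ndarray]


def _spatial_template(
    shape: tuple[int, int], kind: str, rng: np.random.Generator
) -> np.ndarray:
    """Nonnegative spatial intensity template, max 1, zero outside support."""
    if kind == "uniform":
        return np.ones(shape)
    field_ = ndimage.gaussian_filter(
        rng.standard_normal(shape), sigma=max(2.0, min(shape) / 6.0)
    )
    thr = np.quantile(field_, 0.6)
    tmpl = np.clip(field_ - thr, 0.0, None)
    if kind == "region":
        tmpl = (tmpl > 0).astype(float)
    if tmpl.max() == 0:  # pragma: no cover - degenerate random field
        tmpl[shape[0] // 2, shape[1] // 2] = 1.0
    return tmpl / tmpl.max()


def _add_shoulders(
    mzs: list[float], intens: list[float], n_side: int = 3, spacing_ppm: float = 0.8
) -> tuple[list[float], list[float]]:
    """Expand each peak into a dense cluster of sub-tolerance satellites."""
    out_mz: list[float] = []
    out_in: list[float] = []
    for mz, inten in zip(mzs, intens):
        for k in range(-n_side, n_side + 1):
            out_mz.append(mz * (1 + k * spacing_ppm * 1e-6))
            out_in.append(inten * 0.5 ** abs(k))
    return out_mz, out_in


def generate_dataset(cfg: SimulationConfig) -> tuple[CentroidedDataset, GroundTruth]:
    """Generate one centroided dataset with planted ions and ground truth."""
    rng = np.random.default_rng(int(cfg.seed) & 0x7FFFFFFF)
    db = cfg.database if cfg.database is not None else toy_database()
    if not db:
        raise ValueError("empty molecule database")
    n_mol = min(cfg.n_molecules, len(db))
    chosen_idx = rng.choice(len(db), size=n_mol, replace=False)
    rows, cols = cfg.grid_shape
    n_pix = rows * cols

    planted: list[tuple[str, str]] = []
    snr: dict[tuple[str, str], float] = {}
    masks: dict[tuple[str, str], np.ndarray] = {}
    # per-pixel peak accumulators
    pix_mz: list[list[float]] = [[] for _ in range(n_pix)]
    pix_in: list[list[float]] = [[] for _ in range(n_pix)]

    for j, mol_i in enumerate(chosen_idx):
        rec = db[int(mol_i)]
        adduct = cfg.adducts[j % len(cfg.adducts)]
        pattern = pattern_for(rec.formula, adduct, cfg.polarity, T=cfg.T)
        tmpl = _spatial_template(cfg.grid_shape, cfg.spatial_pattern, rng)
        key = (rec.formula, adduct)
        planted.append(key)
        masks[key] = tmpl > 0
        snr[key] = float(cfg.snr)
        support = np.flatnonzero(tmpl.ravel())
        for p in support:
            level = tmpl.ravel()[p]
            mults = rng.lognormal(0.0, 0.1, size=len(pattern.mzs)) if cfg.snr < np.inf else np.ones(len(pattern.mzs))
            for i, (mz_t, rel) in enumerate(
                zip(pattern.mzs, pattern.rel_intensities)
            ):
                jit = rng.normal(0.0, cfg.jitter_ppm) if cfg.jitter_ppm > 0 else 0.0
                pix_mz[p].append(mz_t * (1 + jit * 1e-6))
                pix_in[p].append(cfg.amplitude * rel * level * mults[i])

    noise_scale = cfg.amplitude / cfg.snr if np.isfinite(cfg.snr) and cfg.snr > 0 else 0.0
    lo, hi = cfg.mz_range
    for p in range(n_pix):
        if cfg.noise_peaks_per_pixel > 0 and noise_scale > 0:
            k = int(rng.poisson(cfg.noise_peaks_per_pixel))
            if k:
                pix_mz[p].extend(rng.uniform(lo, hi, size=k).tolist())
                pix_in[p].extend(rng.exponential(noise_scale, size=k).tolist())

    spectra: dict[int, CentroidedSpectrum] = {}
    coords = np.zeros((n_pix, 2), dtype=np.int64)
    for p in range(n_pix):
        mzs, intens = pix_mz[p], pix_in[p]
        if cfg.profile_mode_shoulders and mzs:
            mzs, intens = _add_shoulders(mzs, intens)
        spectra[p] = CentroidedSpectrum(np.asarray(mzs), np.asarray(intens))
        coords[p] = (p % cols, p // cols)  # row-major, 0-based

    ds = CentroidedDataset(
        spectra=spectra,
        coords=coords,
        polarity=cfg.polarity,
        analyzer=cfg.analyzer,
        source=cfg.source,
        mz_min=lo,
        mz_max=hi,
        metadata=dict(cfg.metadata),
        profile_mode_declared=False,
    )
    return ds, GroundTruth(planted=planted, snr=snr, masks=masks)


def generate_corpus(
    n_datasets: int,
    contexts: tuple[str, ...],
    cfg_template: SimulationConfig,
    seed: int = 0,
) -> tuple[list[tuple[CentroidedDataset, GroundTruth]], dict]:
    """Generate a corpus of datasets spread over context labels.

    Per-dataset seeds are derived from the master seed and recorded in the
    returned manifest, so any member is individually reproducible.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    ds_seeds = rng.integers(0, 2**31 - 1, size=n_datasets)
    corpus = []
    manifest: dict = {"master_seed": int(seed), "datasets": []}
    for i in range(n_datasets):
        context = contexts[i % len(contexts)]
        meta = dict(cfg_template.metadata)
        meta["context"] = context
        meta["dataset_id"] = f"sim{i:03d}"
        cfg = replace(cfg_template, seed=int(ds_seeds[i]), metadata=meta)
        corpus.append(generate_dataset(cfg))
        manifest["datasets"].append(
            {"dataset_id": meta["dataset_id"], "context": context, "seed": int(ds_seeds[i])}
        )
    return corpus, manifest


def generate_feature_corpus(
    n_datasets: int = 20,
    n_targets: int = 20,
    n_decoys: int = 100,
    contexts: tuple[str, ...] = ("ctx_a", "ctx_b"),
    informative: dict[str, float] | None = None,
    separation: float = 1.0,
    shuffle_labels: bool = False,
    seed: int = 0,
):
    """Feature-level corpus with a planted informativeness profile.

    Emits, per dataset, feature vectors for targets and decoys drawn so
    that each feature named in ``informative`` separates the two classes
    with the given strength: 1 means disjoint class distributions, values
    in (0, 1) mean overlapping Gaussians whose means move apart with the
    strength, 0 (or unnamed) means identically distributed.  Used to
    exercise the ranker (cross-validation, attribution recovery) without
    paying for full spectra simulation.  ``shuffle_labels`` permutes the
    target/decoy labels within each dataset after the features are drawn,
    destroying the feature-label association (null corpus).

    Returns a pandas DataFrame with dataset_id, context, is_decoy and the
    five features.
    """
    import pandas as pd

    if informative is None:
        informative = {"rho_spectral": 1.0, "rho_spatial": 1.0}
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    rows = []
    for d in range(n_datasets):
        ds_id = f"fc{d:03d}"
        context = contexts[d % len(contexts)]
        labels = np.array([False] * n_targets + [True] * n_decoys)
        for is_decoy in labels:
            feats = {}
            for name in FEATURE_NAMES:
                strength = float(informative.get(name, 0.0)) * separation
                if strength <= 0:
                    feats[name] = rng.uniform(0.2, 0.8)
                elif strength >= 1:
                    feats[name] = (
                        rng.uniform(0.0, 0.35) if is_decoy else rng.uniform(0.65, 1.0)
                    )
                else:
                    mean = 0.5 - 0.4 * strength if is_decoy else 0.5 + 0.4 * strength
                    feats[name] = float(np.clip(rng.normal(mean, 0.15), 0.0, 1.0))
            rows.append(
                {"dataset_id": ds_id, "context": context, "is_decoy": bool(is_decoy), **feats}
            )
        if shuffle_labels:
            shuffled = labels.copy()
            rng.shuffle(shuffled)
            for offset, is_decoy in enumerate(shuffled):
                rows[len(rows) - len(labels) + offset]["is_decoy"] = bool(is_decoy)
    return pd.DataFrame(rows)


def simulate_exchangeable_ranking(
    n_true: int = 30,
    n_false: int = 30,
    S_D: int = 20,
    seed: int = 0,
) -> tuple[list[tuple[dict, float]], list[tuple[dict, float]]]:
    """Scored targets and decoys where false targets are exchangeable with decoys.

    True targets score high (N(3, 1)); false targets and all decoys draw
    from the same null N(0, 1).  Under this exchangeability the estimated
    FDR should bound the realized false-target fraction.  Each target ion
    carries ``{"is_false": bool}``; decoys carry ``{}``.
    """
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    targets = [
        ({"is_false": False}, float(s)) for s in rng.normal(3.0, 1.0, size=n_true)
    ]
    targets += [
        ({"is_false": True}, float(s)) for s in rng.normal(0.0, 1.0, size=n_false)
    ]
    decoys = [
        ({}, float(s))
        for s in rng.normal(0.0, 1.0, size=(n_true + n_false) * S_D)
    ]
    return targets, decoys
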