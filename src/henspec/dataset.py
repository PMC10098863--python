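"""Feature-map dataset assembly: transform, normalize, split, persist.

Labeled reflectance curves become labeled scalogram feature maps (one
wavelet transform per spectrum), each map is min–max scaled to [0, 1]
independently, and the collection is divided 4:1 into training and
validation sets with a seeded, stratified shuffle. Stratification uses
largest-remainder rounding so the per-class proportions of the split
match the whole to within one sample per class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import fcwt
from .synth import LabeledSpectrum, largest_remainder_counts

__all__ = [
    "FeatureDataset",
    "spectra_to_features",
    "normalize_features",
    "train_val_split",
    "save_dataset",
    "load_dataset",
]


@dataclass
class FeatureDataset:
    """Parallel arrays of feature maps and labels plus provenance metadata.

    ``features`` is an (N, n_scales, L) array, ``labels`` an (N,) array
    of class-name strings; ``meta`` records generation parameters.
    """

    features: np.ndarray
    labels: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 3:
            raise ValueError("features must be (N, n_scales, L)")
        if self.labels.shape != (self.features.shape[0],):
            raise ValueError("labels must parallel features")

    def __len__(self) -> int:
        return self.features.shape[0]

    @property
    def class_names(self) -> list[str]:
        return sorted(set(self.labels.tolist()))


def spectra_to_features(
    spectra: Sequence[LabeledSpectrum],
    scales: Optional[fcwt.ScaleSequence] = None,
    omega0: float = fcwt.DEFAULT_OMEGA0,
) -> FeatureDataset:
    """One scalogram per labeled spectrum, labels carried through."""
    if len(spectra) == 0:
        raise ValueError("no spectra supplied")
    lengths = {s.spectrum.size for s in spectra}
    if len(lengths) != 1:
        raise ValueError(f"spectra have mixed lengths {sorted(lengths)}")
    if scales is None:
        scales = fcwt.default_scales()
    maps = np.stack(
        [
            fcwt.to_feature_map(fcwt.fcwt_transform(s.spectrum, scales, omega0)).values
            for s in spectra
        ]
    )
    labels = np.array([s.label for s in spectra])
    meta = {"n_scales": scales.n, "a_exp": scales.a_exp, "b_exp": scales.b_exp, "omega0": omega0}
    return FeatureDataset(features=maps, labels=labels, meta=meta)


def normalize_features(ds: FeatureDataset, method: str = "per_map") -> FeatureDataset:
    """Min–max scale feature maps to [0, 1]; idempotent for both methods.

    ``method="per_map"`` scales each map by its own min and max
    (constant maps become all-zero). This bounds every input
    identically but also cancels any between-map amplitude difference.
    ``method="global"`` scales all maps by the dataset-wide min and
    max, preserving relative scalogram magnitudes between samples — the
    classification pipeline uses this, because overall scalogram
    magnitude (reflectance level and slope) is exactly what separates
    the classes, and the wavelet row magnitudes would otherwise be
    normalized to the same peak for every bird.
    """
    if len(ds) == 0:
        raise ValueError("empty dataset")
    if method == "per_map":
        lo = ds.features.min(axis=(1, 2), keepdims=True)
        hi = ds.features.max(axis=(1, 2), keepdims=True)
    elif method == "global":
        lo = ds.features.min()
        hi = ds.features.max()
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    span = hi - lo
    safe = np.where(span == 0, 1.0, span)
    out = np.where(span == 0, 0.0, (ds.features - lo) / safe)
    return FeatureDataset(
        features=out, labels=ds.labels.copy(), meta={**ds.meta, "normalization": method}
    )


def _subset(ds: FeatureDataset, idx: np.ndarray, meta_extra: dict) -> FeatureDataset:
    return FeatureDataset(
        features=ds.features[idx], labels=ds.labels[idx], meta={**ds.meta, **meta_extra}
    )


def train_val_split(
    ds: FeatureDataset,
    ratio: tuple[int, int] = (4, 1),
    seed: int = 0,
    stratified: bool = True,
) -> tuple[FeatureDataset, FeatureDataset]:
    """Seeded train/validation partition in the given integer ratio.

    The training size is ``round(N * a / (a + b))``. With
    ``stratified`` (the default) the per-class training counts follow
    largest-remainder rounding of the class proportions, so each class
    lands within one sample of its exact quota; samples are shuffled
    within class by the seeded generator. The two subsets are disjoint
    and exhaustive.
    """
    a, b = ratio
    if a < 1 or b < 1:
        raise ValueError("both ratio parts must be >= 1")
    n = len(ds)
    if n < a + b:
        raise ValueError(f"dataset of {n} samples cannot be split {a}:{b}")
    n_train = int(np.floor(n * a / (a + b) + 0.5))
    rng = np.random.default_rng(seed)

    if stratified:
        classes = ds.class_names
        class_indices = [np.flatnonzero(ds.labels == c) for c in classes]
        counts = np.array([idx.size for idx in class_indices])
        quotas = counts * a / (a + b)
        train_counts = np.floor(quotas).astype(int)
        shortfall = n_train - int(train_counts.sum())
        order = np.argsort(-(quotas - train_counts), kind="stable")
        for i in order[:shortfall]:
            train_counts[i] += 1
        train_idx, val_idx = [], []
        for idx, k in zip(class_indices, train_counts):
            perm = rng.permutation(idx)
            train_idx.append(perm[:k])
            val_idx.append(perm[k:])
        train_idx = np.concatenate(train_idx)
        val_idx = np.concatenate(val_idx)
    else:
        perm = rng.permutation(n)
        train_idx, val_idx = perm[:n_train], perm[n_train:]

    # Shuffle across classes so batches are mixed.
    train_idx = rng.permutation(train_idx)
    val_idx = rng.permutation(val_idx)
    meta = {"split_seed": seed, "split_ratio": list(ratio), "stratified": stratified}
    return (
        _subset(ds, train_idx, {**meta, "split": "train"}),
        _subset(ds, val_idx, {**meta, "split": "val"}),
    )


def save_dataset(ds: FeatureDataset, directory) -> Path:
    """Persist as a directory: one delimited matrix file per sample + manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (fmap, label) in enumerate(zip(ds.features, ds.labels)):
        fname = f"sample_{i:05d}.tsv"
        np.savetxt(directory / fname, fmap, delimiter="\t", fmt="%.8g")
        rows.append({"file": fname, "label": str(label)})
    manifest = {"meta": ds.meta, "samples": rows}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return directory


def load_dataset(directory) -> FeatureDataset:
    """Inverse of :func:`save_dataset`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    maps, labels = [], []
    for row in manifest["samples"]:
        maps.append(np.loadtxt(directory / row["file"], delimiter="\t", ndmin=2))
        labels.append(row["label"])
    return FeatureDataset(features=np.stack(maps), labels=np.array(labels), meta=manifest["meta"])
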