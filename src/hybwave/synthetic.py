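"""Seeded synthetic data generators.

Every stage of the pipeline can be exercised without downloading the real
T1-weighted contrast-enhanced MRI dataset: phantoms stand in for tumor
slices, labeled Gaussian feature matrices (with a known informative subset)
stand in for the selection problem, and piecewise-constant signals stand in
for noisy scan lines.  All generators are pure functions of their spec —
the same spec yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import ellipse

__all__ = [
    "PhantomSpec",
    "FeatureSpec",
    "make_phantom_images",
    "make_feature_dataset",
    "make_noisy_signal",
]

#: slices per synthetic patient, mirroring multi-slice acquisitions
IMAGES_PER_SUBJECT = 4


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the elliptical-tumor phantom generator.

    ``class_effect`` is the between-class mean-intensity separation in
    units of ``noise_sd``; classes also differ in lesion size and
    eccentricity so that both intensity- and shape-sensitive features
    carry signal.
    """

    n_images: int = 100
    image_size: int = 64
    n_classes: int = 3
    class_effect: float = 2.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.class_effect <= 0:
            raise ValueError("class_effect must be > 0")


@dataclass(frozen=True)
class FeatureSpec:
    """Parameters of the labeled feature-matrix generator.

    Informative columns get class-dependent means separated by ``effect``
    (in noise-SD units); the rest are pure standard-normal noise.
    """

    n_samples: int = 200
    n_features: int = 50
    n_informative: int = 5
    n_classes: int = 2
    effect: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative >= self.n_features:
            raise ValueError("n_informative must be < n_features")


def make_phantom_images(spec: PhantomSpec):
    """Generate elliptical "tumor" phantoms with class-dependent lesions.

    Returns ``(images, labels, subject_ids)`` where ``images`` is an
    ``(n, size, size)`` float array, ``labels`` an int vector, and
    ``subject_ids`` strings grouping consecutive images into synthetic
    patients (for subject-wise cross-validation).
    """
    rng = np.random.default_rng(spec.seed)
    n, s = spec.n_images, spec.image_size
    labels = np.arange(n) % spec.n_classes  # balanced up to remainder
    rng.shuffle(labels)
    images = np.empty((n, s, s), dtype=np.float64)
    for i, lab in enumerate(labels):
        img = np.zeros((s, s))
        # class shifts lesion mean intensity, size and eccentricity
        mean_int = 0.5 + lab * spec.class_effect * spec.noise_sd
        r_major = s * (0.12 + 0.05 * lab) * (1.0 + 0.1 * rng.standard_normal())
        ecc = 1.0 - 0.18 * lab
        cy = s / 2 + rng.uniform(-s * 0.08, s * 0.08)
        cx = s / 2 + rng.uniform(-s * 0.08, s * 0.08)
        angle = rng.uniform(0, np.pi)
        rr, cc = ellipse(cy, cx, max(r_major, 2.0), max(r_major * ecc, 2.0),
                         shape=(s, s), rotation=angle)
        img[rr, cc] = mean_int
        img += rng.normal(0.0, spec.noise_sd, size=(s, s))
        images[i] = img
    subject_ids = np.array(
        [f"S{(i // IMAGES_PER_SUBJECT):04d}" for i in range(n)]
    )
    return images, labels.astype(int), subject_ids


def make_feature_dataset(spec: FeatureSpec):
    """Generate ``(features, labels, true_mask)`` with known informative columns.

    The informative columns occupy random positions; ``true_mask`` marks
    them.  Class k's informative means sit at ``k * effect`` so adjacent
    classes are separated by ``effect`` noise SDs.
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_samples, spec.n_features
    labels = np.arange(n) % spec.n_classes
    rng.shuffle(labels)
    features = rng.standard_normal((n, d))
    informative = rng.choice(d, size=spec.n_informative, replace=False)
    for j in informative:
        features[:, j] += labels * spec.effect
    true_mask = np.zeros(d, dtype=bool)
    true_mask[informative] = True
    return features, labels.astype(int), true_mask


def make_noisy_signal(length, edge_positions, amplitudes, noise_sd, seed):
    """Piecewise-constant 1-D signal plus Gaussian noise.

    ``clean[i]`` is the cumulative sum of step ``amplitudes`` whose
    ``edge_positions`` are <= i.  Returns ``(clean, noisy)``.
    """
    edge_positions = np.asarray(edge_positions, dtype=int)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if edge_positions.shape != amplitudes.shape:
        raise ValueError("edge_positions and amplitudes must align")
    if np.any((edge_positions < 0) | (edge_positions >= length)):
        raise ValueError("edge positions out of range")
    clean = np.zeros(length)
    for pos, amp in zip(edge_positions, amplitudes):
        clean[pos:] += amp
    rng = np.random.default_rng(seed)
    noisy = clean + rng.normal(0.0, noise_sd, size=length)
    return clean, noisy
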