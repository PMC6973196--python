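"""Synthetic imbalanced microarray-like data with controllable class structure.

Real microarray studies have few samples (tens to ~220), thousands of
genes, imbalanced classes and only a minority of class-informative genes.
The generator emulates that regime: the first ``n_informative`` genes carry
class structure, the rest are pure Gaussian noise, and the whole matrix is
shifted/scaled into a positive expression-like range (min-max scaling
erases location and scale downstream, so a simple affine map suffices).

Structures:

* ``linear`` — class c shifts each informative gene's mean by
  c * effect_size noise-SD units (random sign per gene): classes are
  linearly separable for large effects.
* ``radial`` — classes sit on concentric shells of radius
  effect_size * (1 + 2c) noise-SD units in the informative subspace:
  separable by a local (Gaussian-type) kernel but not by a hyperplane.
* ``mixed`` — first half of the informative genes linear, second half
  radial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionMatrix

STRUCTURES = ("linear", "radial", "mixed")

#: Class sizes and gene counts of the four reference microarray datasets.
#: St. Jude's seventh class is the heterogeneous "other" group, generated
#: diffuse (no informative structure).
REFERENCE_SHAPES: dict[str, dict] = {
    "colon": {"class_sizes": (40, 22), "n_genes": 2000, "diffuse_classes": ()},
    "aml_all": {"class_sizes": (47, 25), "n_genes": 7129, "diffuse_classes": ()},
    "st_jude": {
        "class_sizes": (9, 18, 42, 14, 28, 52, 52),
        "n_genes": 12558,
        "diffuse_classes": (6,),
    },
    "lung": {"class_sizes": (139, 21, 20, 6, 17), "n_genes": 3312, "diffuse_classes": ()},
}


@dataclass
class SynthSpec:
    """Recipe for one synthetic dataset.

    ``effect_size`` is the class-mean separation in noise-SD units;
    ``diffuse_classes`` lists classes generated without informative
    structure (heterogeneous catch-all groups).
    """

    class_sizes: tuple[int, ...]
    n_genes: int
    n_informative: int = 20
    effect_size: float = 3.0
    structure: str = "linear"
    noise_sd: float = 1.0
    seed: int = 0
    diffuse_classes: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.class_sizes):
            raise ValueError("every class size must be >= 1")
        if not 0 < self.n_informative <= self.n_genes:
            raise ValueError("need 0 < n_informative <= n_genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if any(not 0 <= c < len(self.class_sizes) for c in self.diffuse_classes):
            raise ValueError("diffuse_classes out of range")


def _linear_offsets(spec, rng, genes: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-sample mean shifts: evenly spaced class means, random sign per gene."""
    signs = rng.choice([-1.0, 1.0], size=len(genes))
    shift = np.zeros((len(labels), len(genes)))
    for c in range(len(spec.class_sizes)):
        if c in spec.diffuse_classes:
            continue
        rows = labels == c
        shift[rows] = c * spec.effect_size * spec.noise_sd * signs
    return shift


def _radial_offsets(spec, rng, genes: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Concentric-shell structure: class c at radius effect*(1+2c) noise-SDs."""
    p = len(genes)
    offsets = np.zeros((len(labels), p))
    for c in range(len(spec.class_sizes)):
        rows = np.flatnonzero(labels == c)
        if c in spec.diffuse_classes or len(rows) == 0:
            continue
        directions = rng.normal(size=(len(rows), p))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        radius = spec.effect_size * (1.0 + 2.0 * c) * spec.noise_sd
        offsets[rows] = radius * directions
    return offsets


def generate_dataset(spec: SynthSpec) -> ExpressionMatrix:
    """Draw one dataset per the spec; fully reproducible from ``spec.seed``.

    The first ``spec.n_informative`` genes are the informative block (in
    gene order g0000, g0001, ...); everything else is noise.
    """
    rng = np.random.default_rng(spec.seed)
    m = int(sum(spec.class_sizes))
    labels = np.repeat(np.arange(len(spec.class_sizes)), spec.class_sizes)
    values = rng.normal(0.0, spec.noise_sd, size=(m, spec.n_genes))

    info = np.arange(spec.n_informative)
    if spec.structure == "linear":
        values[:, info] += _linear_offsets(spec, rng, info, labels)
    elif spec.structure == "radial":
        values[:, info] += _radial_offsets(spec, rng, info, labels)
    else:  # mixed: half linear, half radial
        half = max(1, spec.n_informative // 2)
        values[:, info[:half]] += _linear_offsets(spec, rng, info[:half], labels)
        values[:, info[half:]] += _radial_offsets(spec, rng, info[half:], labels)

    # expression-like positive range; min-max scaling erases this downstream
    values = 10.0 * (values - values.min()) + 10.0

    width = max(4, len(str(spec.n_genes - 1)))
    return ExpressionMatrix(
        values=values,
        sample_ids=[f"s{i:04d}" for i in range(m)],
        gene_ids=[f"g{j:0{width}d}" for j in range(spec.n_genes)],
        labels=labels,
        class_names=[f"class{c}" for c in range(len(spec.class_sizes))],
    )


def paperlike(name: str, scale: float = 1.0, **overrides) -> ExpressionMatrix:
    """Synthetic stand-in shaped like one of the reference datasets.

    Class and gene counts are scaled by ``scale`` (floored, with at least 2
    samples per class).  Keyword overrides feed through to
    :class:`SynthSpec` (e.g. ``structure``, ``effect_size``, ``seed``).
    """
    if name not in REFERENCE_SHAPES:
        raise ValueError(f"unknown dataset name {name!r}; choose from {sorted(REFERENCE_SHAPES)}")
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    shape = REFERENCE_SHAPES[name]
    class_sizes = tuple(max(2, int(s * scale)) for s in shape["class_sizes"])
    n_genes = max(20, int(shape["n_genes"] * scale))
    spec_kw = {
        "class_sizes": class_sizes,
        "n_genes": n_genes,
        "diffuse_classes": shape["diffuse_classes"],
        "n_informative": min(20, n_genes),
    }
    spec_kw.update(overrides)
    return generate_dataset(SynthSpec(**spec_kw))
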