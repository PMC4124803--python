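"""Seeded synthetic expression data with planted cluster structure.

The generator emulates the structure of a bulk expression study used to
demonstrate clustered heatmaps: samples fall into a small number of
latent groups; a fraction of genes is "informative" (cluster-specific
mean shift, the clusters' mean profiles separated by ``effect_size``
standard-deviation units); the rest is N(0, 1) noise.  A binary (or
multi-level) phenotype agrees with the latent cluster label with
probability ``assoc_strength``, and an "age" column is drawn
independently of the clusters so associations tests have a true null to
report.

Sub-streams are keyed deterministically per component (matrix,
phenotype, age), so adding a phenotype never perturbs the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, InputError, PhenotypeColumn, PhenotypeTable

# component keys for per-stream sub-seeding
_STREAM_MATRIX, _STREAM_PHENOTYPE, _STREAM_AGE, _STREAM_DIRECTION = 0, 1, 2, 3


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset.

    Defaults describe a clearly separable two-group bulk design: 500
    genes x 60 samples, half the genes informative with a 6-sd separation
    between cluster mean profiles, and a binary phenotype agreeing with
    the cluster label 90% of the time.
    """

    n_genes: int = 500
    n_samples: int = 60
    n_clusters: int = 2
    effect_size: float = 6.0
    frac_informative: float = 0.5
    assoc_strength: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.frac_informative <= 1:
            raise InputError("frac_informative must be in [0, 1]")
        if not 0.5 <= self.assoc_strength <= 1:
            raise InputError("assoc_strength must be in [0.5, 1]")
        if not 1 <= self.n_clusters <= self.n_samples:
            raise InputError("need 1 <= n_clusters <= n_samples")
        if self.n_genes < 1 or self.n_samples < 1:
            raise InputError("n_genes and n_samples must be positive")


def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed), stream]))


def make_fixture(spec: FixtureSpec) -> tuple[ExpressionMatrix, PhenotypeTable, np.ndarray]:
    """Generate (matrix, phenotypes, true cluster labels), deterministic per seed."""
    n_inf = int(round(spec.frac_informative * spec.n_genes))
    labels = np.arange(spec.n_samples) % spec.n_clusters  # balanced assignment

    rng_dir = _rng(spec, _STREAM_DIRECTION)
    # random up/down direction per informative gene, so signal is not one-sided
    directions = rng_dir.choice([-1.0, 1.0], size=n_inf)

    rng_m = _rng(spec, _STREAM_MATRIX)
    values = rng_m.normal(0.0, 1.0, size=(spec.n_genes, spec.n_samples))
    if spec.n_clusters > 1 and n_inf > 0:
        # cluster mean profiles spaced effect_size sd units apart end to end
        centers = (labels / (spec.n_clusters - 1) - 0.5) * spec.effect_size
        values[:n_inf, :] += directions[:, None] * centers[None, :]

    gene_names = [f"G{i + 1:04d}" for i in range(spec.n_genes)]
    sample_names = [f"S{j + 1:03d}" for j in range(spec.n_samples)]
    matrix = ExpressionMatrix(values, gene_names, sample_names)

    rng_p = _rng(spec, _STREAM_PHENOTYPE)
    agree = rng_p.random(spec.n_samples) < spec.assoc_strength
    if spec.n_clusters == 2:
        level = {0: "Negative", 1: "Positive"}
        observed = np.where(agree, labels, 1 - labels)
        status = [level[int(v)] for v in observed]
    else:
        flips = rng_p.integers(1, max(spec.n_clusters, 2), size=spec.n_samples)
        observed = np.where(agree, labels, (labels + flips) % spec.n_clusters)
        status = [f"C{int(v) + 1}" for v in observed]

    rng_a = _rng(spec, _STREAM_AGE)
    age = rng_a.normal(60.0, 10.0, size=spec.n_samples)

    phenotypes = PhenotypeTable(sample_names, [
        PhenotypeColumn("status", "categorical", status),
        PhenotypeColumn("age", "continuous", list(age)),
    ])
    return matrix, phenotypes, labels
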