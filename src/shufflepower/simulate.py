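"""Synthetic negative-binomial count generator with known ground truth.

Emulates the statistical structure of a two-diet (CD vs HFD) germ-cell
RNA-seq count table: several annotation classes of configurable size, a
log10-normal spectrum of baseline means spanning several decades, an
overdispersion parameter that decays with the mean following the
hyperbolic trend ``alpha(mu) = a0 + a1 / mu``, unequal library depths, and
an optional fraction of truly differentially expressed annotations with
configurable log2 fold changes.  Counts for annotation *i* in sample *j*
are drawn as

    K_ij ~ NB(mean = s_j * mu_i * 2^(x_j * beta_i),  var = mu + alpha * mu^2)

with ``x_j`` the 0/1 treatment indicator and ``beta_i`` the true log2 fold
change.  The generator returns the count matrix together with a per-row
ground-truth table so that recovery, type-I-error and power behaviour of
the downstream pipeline can be tested without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .countmatrix import REFERENCE_LEVEL, TREATMENT_LEVEL, CountMatrix


class SimConfigError(ValueError):
    """Raised when a SimConfig field is invalid; names the offending field."""


@dataclass
class SimConfig:
    """Parameters of the synthetic count generator.

    Attributes
    ----------
    n_annotations_per_class
        Mapping of class label to number of annotations. Desk-scale
        defaults (2,000 protein-coding, 300 miRNA) keep simulations fast;
        the full published annotation universe is reachable by passing
        larger values.
    n_per_group
        Samples per diet group (the study design used 4 + 4).
    mean_log_mu, sd_log_mu
        Location and spread of the log10 baseline-mean distribution.
        Defaults put roughly 7% of annotations below mean count 1 so the
        low-count filter is exercised.
    dispersion_intercept, dispersion_slope
        a0 and a1 of the trend alpha(mu) = a0 + a1/mu (var = mu + alpha mu^2).
    de_fraction
        Fraction of annotations given a nonzero true log2 fold change.
    de_log2fc_range
        (lo, hi): true effects are drawn uniformly from ±[lo, hi] with a
        random sign.
    library_size_factors
        Per-sample relative depth multipliers; length 2 * n_per_group, or
        None for equal depths.
    seed
        RNG seed; identical seeds give bit-identical output.
    """

    n_annotations_per_class: dict[str, int] = field(
        default_factory=lambda: {"protein_coding": 2000, "miRNA": 300}
    )
    n_per_group: int = 4
    mean_log_mu: float = 1.5
    sd_log_mu: float = 1.0
    dispersion_intercept: float = 0.05
    dispersion_slope: float = 2.0
    de_fraction: float = 0.0
    de_log2fc_range: tuple[float, float] = (0.5, 2.0)
    library_size_factors: np.ndarray | None = None
    seed: int = 0

    def validate(self) -> None:
        if not self.n_annotations_per_class:
            raise SimConfigError("n_annotations_per_class: must be non-empty")
        for cls, n in self.n_annotations_per_class.items():
            if int(n) < 1:
                raise SimConfigError(f"n_annotations_per_class[{cls!r}]: must be >= 1")
        if self.n_per_group < 2:
            raise SimConfigError("n_per_group: must be >= 2")
        if self.sd_log_mu <= 0:
            raise SimConfigError("sd_log_mu: must be > 0")
        if self.dispersion_intercept <= 0:
            raise SimConfigError("dispersion_intercept: must be > 0")
        if self.dispersion_slope < 0:
            raise SimConfigError("dispersion_slope: must be >= 0")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise SimConfigError("de_fraction: must be in [0, 1]")
        lo, hi = self.de_log2fc_range
        if lo < 0 or hi < lo:
            raise SimConfigError("de_log2fc_range: need 0 <= lo <= hi")
        if self.library_size_factors is not None:
            sf = np.asarray(self.library_size_factors, dtype=float)
            if sf.shape != (2 * self.n_per_group,):
                raise SimConfigError(
                    "library_size_factors: length must equal 2 * n_per_group"
                )
            if np.any(sf <= 0):
                raise SimConfigError("library_size_factors: all must be > 0")


def nb_sample(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Draw NB counts in the mean/dispersion parameterisation var = mu + alpha mu^2.

    Implemented as a gamma-Poisson mixture, which is exact for the NB and
    degrades gracefully to Poisson as alpha -> 0.
    """
    mean = np.asarray(mean, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    tiny = alpha < 1e-12
    if np.any(tiny):
        out[tiny] = rng.poisson(mean[tiny])
    big = ~tiny
    if np.any(big):
        shape = 1.0 / alpha[big]
        lam = rng.gamma(shape, alpha[big] * mean[big])
        out[big] = rng.poisson(lam)
    return out


def generate_counts(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate a count matrix and its paired ground-truth table.

    Returns
    -------
    cm : CountMatrix
        Counts with CD samples first, HFD samples second, class labels per
        annotation, and the seed recorded in ``cm.meta``.
    truth : DataFrame
        One row per annotation: class, true baseline mean ``true_mu``,
        ``true_log2fc`` (HFD vs CD) and ``true_dispersion``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    classes: list[str] = []
    ids: list[str] = []
    for cls, n in config.n_annotations_per_class.items():
        classes.extend([cls] * int(n))
        ids.extend(f"{cls}_{k:05d}" for k in range(int(n)))
    n_ann = len(ids)
    n = config.n_per_group

    mu = 10.0 ** rng.normal(config.mean_log_mu, config.sd_log_mu, size=n_ann)
    alpha = config.dispersion_intercept + config.dispersion_slope / mu

    log2fc = np.zeros(n_ann)
    n_de = int(round(config.de_fraction * n_ann))
    if n_de > 0:
        de_idx = rng.choice(n_ann, size=n_de, replace=False)
        lo, hi = config.de_log2fc_range
        mag = rng.uniform(lo, hi, size=n_de)
        sign = rng.choice([-1.0, 1.0], size=n_de)
        log2fc[de_idx] = mag * sign

    if config.library_size_factors is None:
        sf = np.ones(2 * n)
    else:
        sf = np.asarray(config.library_size_factors, dtype=float)

    indicator = np.concatenate([np.zeros(n), np.ones(n)])
    # mean matrix: annotations x samples
    mean = mu[:, None] * (2.0 ** (log2fc[:, None] * indicator[None, :])) * sf[None, :]
    counts = nb_sample(rng, mean, alpha[:, None])

    sample_ids = [f"CD_{k + 1}" for k in range(n)] + [f"HFD_{k + 1}" for k in range(n)]
    groups = pd.Series(
        [REFERENCE_LEVEL] * n + [TREATMENT_LEVEL] * n, index=sample_ids
    )
    cm = CountMatrix(
        pd.DataFrame(counts, index=ids, columns=sample_ids),
        groups,
        pd.Series(classes, index=ids),
        meta={"seed": config.seed, "generator": "shufflepower.simulate"},
    )
    truth = pd.DataFrame(
        {
            "class": classes,
            "true_mu": mu,
            "true_log2fc": log2fc,
            "true_dispersion": alpha,
        },
        index=pd.Index(ids, name="annotation_id"),
    )
    return cm, truth


def generate_null_counts(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """As :func:`generate_counts` with the DE fraction forced to zero."""
    from dataclasses import replace

    return generate_counts(replace(config, de_fraction=0.0))
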