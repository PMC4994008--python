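"""Post hoc power analysis by count shuffling and spike-in.

The idea: build simulated annotations whose counts are real observed
counts, rearranged.  A simulated annotation takes its control-diet block
of counts from one randomly chosen real annotation and its high-fat-diet
block from another — counts move between annotations but never between
treatment groups, so the marginal count distribution and the experimental
design are preserved exactly.  Each simulated annotation carries a
realised log2 fold change (the log2 ratio of its size-factor-normalised
group means); simulated annotations are retained while |log2FC| falls in
a class-specific window (0.0–2.0 for protein-coding genes, 0.0–0.5 for
miRNAs in the source design).  Retained spikes are appended to the real
table and the full differential-expression pipeline is re-run on the
combined table.  Power per 0.1-wide |log2FC| bin is the fraction of
spiked annotations in the bin that come out significant; the minimal
reliably detectable effect is read off the resulting power curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .countmatrix import CountMatrix
from .de import estimate_size_factors, filter_low_counts, run_de

SPIKE_PREFIX = "SPIKE_"
BIN_WIDTH = 0.1


@dataclass
class ShuffleSpec:
    """Parameters of the shuffle construction.

    fc_window : (lo, hi) of admissible |log2FC| for retained spikes.
    n_spike_target : number of simulated annotations to retain.
    max_iterations : bound on shuffle attempts.
    pseudocount : added to normalised group means before the log-ratio.
    seed : RNG seed for the pairing draws.
    """

    fc_window: tuple[float, float] = (0.0, 2.0)
    n_spike_target: int = 1000
    max_iterations: int = 1_000_000
    pseudocount: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.fc_window
        if lo < 0 or hi < lo:
            raise ValueError("fc_window: need 0 <= lo <= hi")
        if self.n_spike_target < 1:
            raise ValueError("n_spike_target must be >= 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


@dataclass
class SpikeSet:
    """Shuffled-and-filtered simulated annotations.

    counts : spike × sample integer counts, columns aligned with the host.
    realised_log2fc : per spike, log2 of normalised HFD vs CD group means.
    provenance : per spike, (CD-block source id, HFD-block source id).
    """

    counts: pd.DataFrame
    realised_log2fc: pd.Series
    provenance: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.counts.shape[0]


def shuffle_counts(cm: CountMatrix, spec: ShuffleSpec) -> SpikeSet:
    """Generate spike annotations by within-group block pairing.

    Iteratively pairs the CD block of one host annotation with the HFD
    block of another (both drawn uniformly at random), computes the
    realised log2FC on size-factor-normalised group means with the
    pseudocount, and retains the pair iff |log2FC| lies in the window.
    Stops at ``n_spike_target`` retained spikes or ``max_iterations``
    attempts, whichever comes first (a short set triggers a warning).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sf = estimate_size_factors(cm)
    counts = cm.counts.to_numpy(dtype=np.int64)
    norm = counts / sf.to_numpy()[None, :]
    ref, treat = cm.levels
    cd = cm.group_mask(ref)
    hfd = cm.group_mask(treat)
    mean_cd = norm[:, cd].mean(axis=1)
    mean_hfd = norm[:, hfd].mean(axis=1)
    n_ann = cm.n_annotations
    lo, hi = spec.fc_window
    pc = spec.pseudocount

    kept_cd_idx: list[np.ndarray] = []
    kept_hfd_idx: list[np.ndarray] = []
    n_kept = 0
    attempts = 0
    batch = max(1024, 2 * spec.n_spike_target)
    while n_kept < spec.n_spike_target and attempts < spec.max_iterations:
        m = min(batch, spec.max_iterations - attempts)
        i_cd = rng.integers(0, n_ann, size=m)
        i_hfd = rng.integers(0, n_ann, size=m)
        attempts += m
        lfc = np.log2((mean_hfd[i_hfd] + pc) / (mean_cd[i_cd] + pc))
        ok = (np.abs(lfc) >= lo) & (np.abs(lfc) <= hi)
        kept_cd_idx.append(i_cd[ok])
        kept_hfd_idx.append(i_hfd[ok])
        n_kept += int(ok.sum())

    i_cd = np.concatenate(kept_cd_idx)[: spec.n_spike_target]
    i_hfd = np.concatenate(kept_hfd_idx)[: spec.n_spike_target]
    if len(i_cd) < spec.n_spike_target:
        warnings.warn(
            f"only {len(i_cd)} of {spec.n_spike_target} spikes retained "
            f"after {attempts} attempts",
            stacklevel=2,
        )

    spike_counts = np.empty((len(i_cd), cm.n_samples), dtype=np.int64)
    spike_counts[:, cd] = counts[np.ix_(i_cd, np.where(cd)[0])]
    spike_counts[:, hfd] = counts[np.ix_(i_hfd, np.where(hfd)[0])]
    realised = np.log2((mean_hfd[i_hfd] + pc) / (mean_cd[i_cd] + pc))
    ids = pd.Index([f"{SPIKE_PREFIX}{k:06d}" for k in range(len(i_cd))])
    ann_ids = cm.annotation_ids
    return SpikeSet(
        counts=pd.DataFrame(spike_counts, index=ids, columns=cm.sample_ids.copy()),
        realised_log2fc=pd.Series(realised, index=ids, name="realised_log2fc"),
        provenance=pd.DataFrame(
            {"cd_source": ann_ids[i_cd], "hfd_source": ann_ids[i_hfd]}, index=ids
        ),
        meta={"seed": spec.seed, "attempts": attempts, "fc_window": spec.fc_window},
    )


def spike_in(cm: CountMatrix, spikes: SpikeSet, spike_class: str | None = None) -> CountMatrix:
    """Append the spike rows to the host table under reserved ids.

    Spiked annotations inherit the host class (``spike_class`` when the
    host carries several classes).
    """
    if len(spikes) == 0:
        return CountMatrix(cm.counts, cm.groups, cm.classes, dict(cm.meta))
    if spikes.counts.index.isin(cm.annotation_ids).any():
        raise ValueError("spike ids collide with host annotation ids")
    if not spikes.counts.columns.equals(cm.sample_ids):
        raise ValueError("spike columns do not align with host samples")
    host_classes = cm.class_names()
    if spike_class is None:
        if len(host_classes) != 1:
            raise ValueError("host has several classes; pass spike_class")
        spike_class = host_classes[0]
    combined = pd.concat([cm.counts, spikes.counts])
    classes = pd.concat(
        [cm.classes, pd.Series(spike_class, index=spikes.counts.index)]
    )
    return CountMatrix(combined, cm.groups, classes, dict(cm.meta))


@dataclass
class PowerCurve:
    """Detection power per |log2FC| bin of width 0.1.

    power_per_bin is NaN for empty bins (power undefined, not zero).
    ``overall_proportion_spiked`` is significant spikes / all spikes;
    ``overall_proportion_class`` uses all tested annotations of the class
    as denominator (the class-relative reading).
    """

    bin_edges: np.ndarray
    power_per_bin: np.ndarray
    n_spiked_per_bin: np.ndarray
    n_significant_per_bin: np.ndarray
    alpha_sig: float
    overall_proportion_spiked: float
    overall_proportion_class: float

    @property
    def bin_midpoints(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "n_spiked": self.n_spiked_per_bin,
                "n_significant": self.n_significant_per_bin,
                "power": self.power_per_bin,
            }
        )


def _bin_power(
    realised: np.ndarray, significant: np.ndarray, fc_hi: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    n_bins = int(np.ceil(round(fc_hi / BIN_WIDTH, 9))) or 1
    edges = np.round(np.arange(n_bins + 1) * BIN_WIDTH, 10)
    idx = np.clip(np.floor(np.abs(realised) / BIN_WIDTH).astype(int), 0, n_bins - 1)
    n_spiked = np.bincount(idx, minlength=n_bins)
    n_sig = np.bincount(idx, weights=significant.astype(float), minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        power = np.where(n_spiked > 0, n_sig / n_spiked, np.nan)
    return edges, power, n_spiked, n_sig.astype(int)


def run_power_analysis(
    cm: CountMatrix,
    spec: ShuffleSpec,
    alpha_sig: float = 0.05,
    spike_class: str | None = None,
) -> tuple[PowerCurve, pd.DataFrame]:
    """Shuffle, spike in, re-run the DE pipeline, and bin detection power.

    Size factors, dispersions, the Wald tests and BH adjustment are all
    re-estimated on the combined table, exactly as for a real analysis.
    Returns the power curve and the combined-table DE result (spike rows
    identifiable by their reserved id prefix).
    """
    spikes = shuffle_counts(cm, spec)
    combined = spike_in(cm, spikes, spike_class=spike_class)
    de_tab = run_de(combined, alpha_sig=alpha_sig)
    is_spike = de_tab.index.str.startswith(SPIKE_PREFIX)
    # a spike that fell below the low-count filter of the combined run was
    # tested-and-missed: it stays in the power denominator as undetected
    spike_rows = de_tab.reindex(spikes.counts.index)
    realised = spikes.realised_log2fc.to_numpy()
    significant = spike_rows["significant"].eq(True).to_numpy(dtype=bool)

    edges, power, n_spiked, n_sig = _bin_power(realised, significant, spec.fc_window[1])
    n_class_tested = int((~is_spike).sum())
    total_spiked = int(len(spikes))
    pc = PowerCurve(
        bin_edges=edges,
        power_per_bin=power,
        n_spiked_per_bin=n_spiked,
        n_significant_per_bin=n_sig,
        alpha_sig=alpha_sig,
        overall_proportion_spiked=(
            float(significant.sum()) / total_spiked if total_spiked else float("nan")
        ),
        overall_proportion_class=(
            float(significant.sum()) / n_class_tested if n_class_tested else float("nan")
        ),
    )
    return pc, de_tab


def detectable_effect(pc: PowerCurve, power_threshold: float = 0.8) -> float:
    """Midpoint of the lowest |log2FC| bin from which power stays >= threshold.

    Scans bins from small to large effect and returns the midpoint of the
    lowest non-empty bin whose power, and the power of every higher
    non-empty bin, reaches the threshold.  Empty bins (undefined power)
    are skipped.  Returns NaN when no bin qualifies.
    """
    power = pc.power_per_bin
    mids = pc.bin_midpoints
    defined = ~np.isnan(power)
    if not defined.any():
        warnings.warn("power curve has no non-empty bin", stacklevel=2)
        return float("nan")
    ok = np.where(defined, power >= power_threshold, True)  # skip empty bins
    # suffix-AND: bin qualifies iff it and all higher bins pass
    qualifies = np.logical_and.accumulate(ok[::-1])[::-1] & defined
    if not qualifies.any():
        warnings.warn("no bin reaches the requested power", stacklevel=2)
        return float("nan")
    return float(mids[np.argmax(qualifies)])
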