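"""Spike-train and population metrics.

Trial-to-trial reliability from Gaussian-convolved spike trains, pooled
firing-rate series, zero-lag Pearson cross-correlation matrices, somatic
IPSC lateral-inhibition curves and firing-rate-change maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .membrane import SpikeTrain


@dataclass
class RateSeries:
    """Binned firing rate (spikes/s) with fixed bin width in ms."""

    bin_width: float
    values: np.ndarray
    label: object = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if np.any(self.values < 0):
            raise ValueError("rates must be >= 0")


@dataclass
class CorrelationMatrix:
    labels: list
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n) or len(self.labels) != n:
            raise ValueError("matrix must be square and match labels")

    def value(self, a, b) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])


def _pair_reliability(t1: np.ndarray, t2: np.ndarray, sigma: float) -> float:
    """Normalized inner product of two Gaussian-convolved spike trains.

    <f1, f2> for unit Gaussians at the spike times reduces to
    sum_ij exp(-(t_i - t_j)^2 / (4 sigma^2)) up to a common constant that
    cancels in the normalization.
    """
    if t1.size == 0 or t2.size == 0:
        return 0.0

    def gram(a, b):
        d = a[:, None] - b[None, :]
        return float(np.sum(np.exp(-(d**2) / (4.0 * sigma**2))))

    num = gram(t1, t2)
    den = np.sqrt(gram(t1, t1) * gram(t2, t2))
    return num / den if den > 0 else 0.0


def reliability(trains: list[SpikeTrain | np.ndarray], sigma: float) -> float:
    """Mean pairwise reliability across trials at Gaussian kernel width sigma.

    Each trial's spike train is convolved with a Gaussian of width
    ``sigma`` (ms); reliability is the mean over trial pairs of the
    normalized inner product of the convolved trains.  All-empty trials
    give 0 by definition.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if len(trains) < 2:
        raise ValueError("need at least two trials")
    arrs = [
        np.asarray(tr.times if isinstance(tr, SpikeTrain) else tr, dtype=float)
        for tr in trains
    ]
    vals = []
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            vals.append(_pair_reliability(arrs[i], arrs[j], sigma))
    return float(np.mean(vals))


def rate_series(
    trains: SpikeTrain | list[SpikeTrain],
    bin_width: float,
    t_start: float = 0.0,
    t_stop: float | None = None,
    label=None,
) -> RateSeries:
    """Pooled population firing rate: histogram counts / bin width.

    Values are spikes/s pooled over the population (not per cell), so
    sum(values) * bin_width[s] equals the total spike count.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if isinstance(trains, (SpikeTrain, np.ndarray)):
        trains = [trains]
    all_t = (
        np.concatenate([
            np.asarray(tr.times if isinstance(tr, SpikeTrain) else tr, dtype=float)
            for tr in trains
        ])
        if trains
        else np.zeros(0)
    )
    if t_stop is None:
        t_stop = float(all_t.max()) + bin_width if all_t.size else t_start + bin_width
    edges = np.arange(t_start, t_stop + bin_width * 0.5, bin_width)
    if edges.shape[0] < 2:
        edges = np.asarray([t_start, t_start + bin_width])
    counts, _ = np.histogram(all_t, edges)
    return RateSeries(bin_width, counts / (bin_width / 1000.0), label)


def cross_correlation(series: list[RateSeries]) -> CorrelationMatrix:
    """Zero-lag Pearson correlation of mean-subtracted rate series.

    Zero-variance series correlate 0 with everything (diagonal stays 1).
    """
    n = len(series)
    lengths = {s.values.shape[0] for s in series}
    if len(lengths) != 1:
        raise ValueError("series must have equal lengths")
    X = np.stack([s.values for s in series])
    X = X - X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if sd[i] == 0 or sd[j] == 0:
                r = 0.0
            else:
                r = float(np.mean(X[i] * X[j]) / (sd[i] * sd[j]))
            mat[i, j] = mat[j, i] = r
    return CorrelationMatrix([s.label for s in series], mat)


def lateral_inhibition_curve(
    net_factory,
    probe_unit: int,
    distances,
    holding: float = -60.0,
    cell_type: str = "MC",
    **probe_kwargs,
) -> np.ndarray:
    """Normalized somatic IPSC peak in a probe cell vs inter-unit distance.

    ``net_factory(distance)`` must return a learned two-unit network whose
    probe unit sits at distance ``distance`` from the stimulated unit (the
    pair geometry is rebuilt per distance so learning is uncontaminated by
    third units).  For each distance the probe principal cell of
    ``cell_type`` is voltage-clamped at ``holding`` mV while the other unit
    is driven; the peak outward clamp current is recorded and the curve is
    normalized to its maximum.  Distances with no synaptic path give 0.
    """
    from .netsim import measure_ipsc_peak

    peaks = []
    for d in distances:
        net = net_factory(d) if callable(net_factory) else net_factory[d]
        peaks.append(
            measure_ipsc_peak(
                net, probe_unit=probe_unit, cell_type=cell_type, holding=holding,
                **probe_kwargs,
            )
        )
    peaks = np.asarray(peaks, dtype=float)
    mx = peaks.max()
    return peaks / mx if mx > 0 else peaks


def firing_rate_map(
    net_factory,
    distance_grid,
    deltaS_grid,
    concentration_drive: float,
    cell_type: str = "MC",
    **run_kwargs,
) -> np.ndarray:
    """Percent firing-rate change of a probe unit vs (distance, dS/S).

    ``net_factory(distance)`` returns a learned two-unit network.  For each
    grid point the probe glomerulus is driven at ``concentration_drive``
    and the co-active glomerulus at S_co = S_probe / (1 + dS/S) (so
    negative dS/S means the probe is the weaker of the pair); the map entry
    is 100 * (rate_with_co_unit - rate_alone) / rate_alone for the probe
    principal cells of ``cell_type``.
    """
    from .netsim import measure_rate_change

    out = np.zeros((len(deltaS_grid), len(distance_grid)))
    for j, d in enumerate(distance_grid):
        net = net_factory(d) if callable(net_factory) else net_factory[d]
        for i, ds in enumerate(deltaS_grid):
            s_probe = concentration_drive
            s_co = s_probe / (1.0 + ds) if ds > -1 else s_probe * 10.0
            out[i, j] = measure_rate_change(
                net, s_probe, s_co, cell_type=cell_type, **run_kwargs
            )
    return out
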