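"""Read-level QC and length stratification for HiFi-like reads.

Consensus generation itself is out of scope; QC consumes already-polished
reads plus their pass-count / predicted-accuracy metadata and applies the
standard inclusive minima (``min_passes >= 3``, ``min_predicted_accuracy >=
0.99``), then optionally stratifies by read length.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import InvalidParameterError
from .simulate import SimRead

log = logging.getLogger(__name__)

Bin = tuple[int, int]


def default_length_bins(genome_length: int = 4700, step: int = 500) -> tuple[Bin, ...]:
    """Half-open length bins in `step` nt increments covering the genome length."""
    top = step * (genome_length // step + 2)  # headroom for insertion-lengthened reads
    edges = list(range(0, top + 1, step))
    return tuple((a, b) for a, b in zip(edges[:-1], edges[1:]))


@dataclass(frozen=True)
class QCParams:
    min_passes: int = 3
    min_predicted_accuracy: float = 0.99
    length_bins: tuple[Bin, ...] = field(default_factory=default_length_bins)

    def __post_init__(self):
        if self.min_passes < 1:
            raise InvalidParameterError("min_passes must be >= 1")
        bins = sorted(self.length_bins)
        if tuple(bins) != tuple(self.length_bins):
            raise InvalidParameterError("length bins must be sorted")
        for (a1, b1), (a2, _) in zip(bins[:-1], bins[1:]):
            if a1 >= b1 or b1 > a2:
                raise InvalidParameterError("length bins must be non-overlapping half-open intervals")


def filter_reads(reads: list[SimRead], params: QCParams = QCParams(),
                 on_missing: str = "drop") -> list[SimRead]:
    """Keep reads meeting both inclusive thresholds, preserving input order.

    Reads lacking metadata are dropped with a warning, or raise when
    ``on_missing='error'``.
    """
    kept: list[SimRead] = []
    dropped = 0
    for r in reads:
        if r.n_passes is None or r.predicted_accuracy is None:
            if on_missing == "error":
                raise InvalidParameterError(f"read {r.id}: missing QC metadata")
            log.warning("read %s: missing QC metadata, dropped", r.id)
            dropped += 1
            continue
        if r.n_passes >= params.min_passes and \
                r.predicted_accuracy >= params.min_predicted_accuracy:
            kept.append(r)
        else:
            dropped += 1
    log.info("QC: kept %d / dropped %d of %d reads", len(kept), dropped, len(reads))
    return kept


def bin_reads_by_length(reads: list[SimRead],
                        bins: tuple[Bin, ...] | None = None) -> dict:
    """Partition reads into half-open length bins; leftovers go to 'unbinned'."""
    if bins is None:
        bins = QCParams().length_bins
    buckets: dict = {b: [] for b in bins}
    buckets["unbinned"] = []
    for r in reads:
        n = len(r.seq)
        for a, b in bins:
            if a <= n < b:
                buckets[(a, b)].append(r)
                break
        else:
            buckets["unbinned"].append(r)
    return buckets


def qc_report(reads: list[SimRead], params: QCParams = QCParams()) -> dict:
    """Counts kept/dropped plus per-bin occupancy of the kept reads."""
    kept = filter_reads(reads, params)
    buckets = bin_reads_by_length(kept, params.length_bins)
    return {
        "n_input": len(reads),
        "n_kept": len(kept),
        "n_dropped": len(reads) - len(kept),
        "bins": {str(k): len(v) for k, v in buckets.items()},
    }
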