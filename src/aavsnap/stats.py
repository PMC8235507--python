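"""Population-level summaries and the breakpoint-randomness test.

The headline statistic formalizes the "no obvious hot spots" observation for
incomplete genomes: if aborted packaging is a random event, ICG breakpoints
should be uniform over the non-ITR interior. We test this with a Pearson
chi-square over equal-width interior bins (bins with expected count < 5 are
merged with their right neighbor, the standard validity rule).
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .classify import ConfigurationCall
from .errors import InvalidParameterError
from .simulate import CATEGORIES


@dataclass
class PopulationSummary:
    n_reads: int
    counts: dict
    fractions: dict
    length_quartiles: dict          # category -> (q1, median, q3)
    sbg_count: int
    icg_count: int
    sbg_icg_ratio: float | None     # ICG / SBG ("ratio of ICG vs SBG")
    symmetric_fraction: float | None
    breakpoint_uniformity: dict | None
    run_totals: dict | None

    def to_json(self, path=None, seed=None) -> str:
        payload = {"aavsnap_seed": seed, **asdict(self)}
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def merge_run_counts(run_sizes: Mapping[str, int] | Sequence[int]) -> dict:
    """Combine per-run read counts from multiple sequencing runs.

    Accepts a mapping run-name -> count or a plain sequence of counts and
    returns per-run totals plus their sum.
    """
    if isinstance(run_sizes, Mapping):
        totals = {str(k): int(v) for k, v in run_sizes.items()}
    else:
        totals = {f"run{i + 1}": int(v) for i, v in enumerate(run_sizes)}
    return {"per_run": totals, "sum": sum(totals.values())}


def breakpoint_uniformity_test(icg_calls, ref=None, n_bins: int = 20,
                               interior: tuple[int, int] | None = None):
    """Pearson chi-square of ICG breakpoints against the uniform expectation.

    ``icg_calls`` may be ConfigurationCalls or raw breakpoint coordinates.
    Returns ``(chi2, df, p)``; raises if fewer than 2 usable bins remain.
    """
    if interior is None:
        if ref is None:
            raise InvalidParameterError("need a reference or an explicit interior interval")
        interior = ref.interior
    lo, hi = interior
    bps = np.asarray([c.breakpoint if isinstance(c, ConfigurationCall) else c
                      for c in icg_calls], dtype=float)
    bps = bps[(bps >= lo) & (bps < hi)]
    n = bps.size
    if n == 0 or n_bins < 2:
        raise InvalidParameterError("need breakpoints and at least 2 bins")
    edges = np.linspace(lo, hi, n_bins + 1)
    obs, _ = np.histogram(bps, bins=edges)
    exp = np.full(n_bins, n / n_bins)
    # merge bins until every expected count is >= 5
    obs, exp = list(obs), list(exp)
    i = 0
    while i < len(exp):
        if exp[i] < 5 and len(exp) > 1:
            j = i + 1 if i + 1 < len(exp) else i - 1
            exp[j] += exp[i]
            obs[j] += obs[i]
            del exp[i], obs[i]
        else:
            i += 1
    if len(exp) < 2:
        raise InvalidParameterError("fewer than 2 usable bins after merging")
    chi2, p = sps.chisquare(obs, exp)
    df = len(exp) - 1
    return float(chi2), int(df), float(p)


def arm_symmetry_histogram(sbg_calls: Iterable[ConfigurationCall],
                           bin_width: int = 100):
    """Histogram of |arm_a - arm_b| (the implied single-strand loop length)."""
    loops = np.asarray([c.loop_len for c in sbg_calls], dtype=float)
    if loops.size == 0:
        return np.empty(0, dtype=int), np.empty(1)
    top = (int(loops.max()) // bin_width + 1) * bin_width
    edges = np.arange(0, top + bin_width, bin_width)
    counts, edges = np.histogram(loops, bins=edges)
    return counts, edges


def category_confusion(truth_labels: Sequence[str],
                       called_labels: Sequence[str]):
    """Truth-by-call confusion matrix (rows: truth) over all categories."""
    import pandas as pd
    idx = list(CATEGORIES)
    mat = pd.DataFrame(0, index=idx, columns=idx, dtype=int)
    for t, c in zip(truth_labels, called_labels):
        mat.loc[t, c] += 1
    return mat


def summarize_population(calls: Sequence[ConfigurationCall],
                         per_run_ids: Mapping | Sequence[int] | None = None,
                         ref=None, n_bins: int = 20,
                         breakpoint_interval: tuple[int, int] | None = None
                         ) -> PopulationSummary:
    """Counts, fractions, length quartiles, ICG:SBG ratio and uniformity test.

    ``per_run_ids`` is either per-run read counts (run -> count, for
    accounting across sequencing runs) or a per-read mapping read_id -> run.
    ``breakpoint_interval`` overrides the interval the uniformity test bins
    (default: the full non-ITR interior); pass the support of the breakpoint
    process when it is narrower, otherwise edge bins are spuriously depleted.
    """
    n = len(calls)
    counts = {c: 0 for c in CATEGORIES}
    for c in calls:
        counts[c.category] += 1
    fractions = {k: (v / n if n else 0.0) for k, v in counts.items()}

    quartiles = {}
    for cat in CATEGORIES:
        lens = [c.read_length for c in calls
                if c.category == cat and c.read_length is not None]
        if lens:
            q1, q2, q3 = np.percentile(lens, [25, 50, 75])
            quartiles[cat] = (float(q1), float(q2), float(q3))

    sbg = counts["SBG_5"] + counts["SBG_3"]
    icg = counts["ICG"]
    ratio = icg / sbg if sbg else None
    sbg_calls = [c for c in calls if c.category.startswith("SBG")]
    sym_frac = (sum(c.subtype == "SYMMETRIC" for c in sbg_calls) / len(sbg_calls)
                if sbg_calls else None)

    uniformity = None
    icg_calls = [c for c in calls if c.category == "ICG" and c.breakpoint is not None]
    if (ref is not None or breakpoint_interval is not None) \
            and len(icg_calls) >= 2 * n_bins:
        chi2, df, p = breakpoint_uniformity_test(
            icg_calls, ref, n_bins, interior=breakpoint_interval)
        uniformity = {"chi2": chi2, "df": df, "p": p}

    run_totals = None
    if per_run_ids is not None:
        if isinstance(per_run_ids, Mapping) and calls and \
                set(per_run_ids) >= {c.read_id for c in calls}:
            by_run: dict[str, int] = {}
            for c in calls:
                by_run[str(per_run_ids[c.read_id])] = \
                    by_run.get(str(per_run_ids[c.read_id]), 0) + 1
            run_totals = merge_run_counts(by_run)
        else:
            run_totals = merge_run_counts(per_run_ids)

    return PopulationSummary(
        n_reads=n, counts=counts, fractions=fractions,
        length_quartiles=quartiles, sbg_count=sbg, icg_count=icg,
        sbg_icg_ratio=ratio, symmetric_fraction=sym_frac,
        breakpoint_uniformity=uniformity, run_totals=run_totals)
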