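"""Count-table preprocessing: subcomposition, seasons, depth filter, zeros.

Raw oligotype read counts are reduced to the subcomposition of interest
(the six dominant oligotypes by default), each dated sample is assigned
to one of three fixed seasons, samples with too few total reads are
dropped, and count zeros are replaced by a seasonal Bayesian-multiplicative
posterior estimate so that the strictly-positive compositions required by
log-ratio geometry exist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date as _date
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import CompositionMatrix, closure

__all__ = [
    "SEASONS",
    "CountTable",
    "ImputationReport",
    "assign_season",
    "season_series",
    "subcomposition",
    "filter_low_depth",
    "impute_zeros",
]

logger = logging.getLogger(__name__)

#: Fixed season strata (month, day boundaries; year-independent):
#: winter_spring = Jan 1 – Jun 15, summer = Jun 16 – Sep 15, fall = Sep 16 – Dec 31.
SEASONS = ("winter_spring", "summer", "fall")


def assign_season(date) -> str:
    """Map a calendar date to its season stratum by month/day.

    Boundaries are inclusive on the left season: Jun 15 is winter_spring,
    Jun 16 summer, Sep 15 summer, Sep 16 fall.  Feb 29 falls in
    winter_spring like any other winter date.
    """
    d = pd.Timestamp(date)
    md = (d.month, d.day)
    if md <= (6, 15):
        return "winter_spring"
    if md <= (9, 15):
        return "summer"
    return "fall"


def season_series(dates: pd.Series) -> pd.Series:
    """Season label per sample for a datetime Series."""
    return pd.Series([assign_season(d) for d in dates], index=dates.index, dtype=object)


@dataclass
class CountTable:
    """n dated samples × D oligotypes of non-negative integer read counts."""

    counts: pd.DataFrame
    dates: pd.Series

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if np.any(vals < 0):
            raise ValueError("negative read count")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("read counts must be integers")
        self.counts = self.counts.astype(np.int64)
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate sample ids in count table")
        self.dates = pd.Series(pd.to_datetime(self.dates), index=self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def part_labels(self) -> tuple[str, ...]:
        return tuple(self.counts.columns)

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    def totals(self) -> pd.Series:
        """Total reads per sample over the current parts."""
        return self.counts.sum(axis=1)

    def seasons(self) -> pd.Series:
        return season_series(self.dates)


def subcomposition(table: CountTable, keep: Sequence[str]) -> CountTable:
    """Restrict (and reorder) the table to the parts in ``keep``.

    Samples whose total over ``keep`` is zero are retained but logged:
    they carry no information about the subcomposition and will be
    rejected downstream (depth filter or imputation).
    """
    missing = [k for k in keep if k not in table.counts.columns]
    if missing:
        raise KeyError(f"unknown part label(s): {missing}")
    sub = table.counts.loc[:, list(keep)]
    empty = sub.sum(axis=1) == 0
    if empty.any():
        logger.warning(
            "samples with zero reads over the subcomposition: %s",
            list(sub.index[empty]),
        )
    return CountTable(sub, table.dates)


def filter_low_depth(table: CountTable, min_reads: int = 15) -> CountTable:
    """Drop samples with fewer than ``min_reads`` total reads.

    Below roughly 15 reads the observed composition is dominated by
    stochastic presence/absence of parts, so such samples are removed
    (their ids are logged).
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    totals = table.totals()
    keep = totals >= min_reads
    removed = list(table.counts.index[~keep])
    if removed:
        logger.info("filter_low_depth(min_reads=%d) removed %d sample(s): %s",
                    min_reads, len(removed), removed)
    if not keep.any():
        logger.warning("all samples fall below min_reads=%d", min_reads)
    return CountTable(table.counts.loc[keep], table.dates.loc[keep])


@dataclass
class ImputationReport:
    """Bookkeeping from zero replacement: priors used, zeros replaced."""

    per_sample: pd.DataFrame  # columns: season, depth, n_zeros, strength
    priors: pd.DataFrame  # season × part prior proportions
    warnings: list[str]


def _stratum_prior(
    counts: pd.DataFrame, props: pd.DataFrame
) -> tuple[np.ndarray, list[str]]:
    """Data-driven prior: closure of geometric means of observed proportions.

    For each part the geometric mean runs over the stratum's samples in
    which that part was detected; a part never detected in the stratum
    falls back to a uniform-share prior value with a warning.
    """
    D = counts.shape[1]
    t = np.empty(D)
    warns: list[str] = []
    for j, col in enumerate(counts.columns):
        obs = props.loc[counts[col] > 0, col]
        if len(obs) == 0:
            t[j] = 1.0 / D
            warns.append(f"part {col}: no non-zero observation in stratum; uniform prior")
        else:
            t[j] = float(np.exp(np.log(obs).mean()))
    return closure(t), warns


def impute_zeros(
    table: CountTable,
    strata: pd.Series | None = None,
    prior_proportions: Mapping[str, Sequence[float]] | None = None,
    strength: str | float = "sqrt",
    return_report: bool = False,
):
    """Seasonal Bayesian-multiplicative zero replacement.

    Within each season stratum a prior composition ``p`` is estimated
    (or supplied); for sample i with read depth ``N_i`` and prior
    strength ``s_i`` each zero part j receives ``p_j * s_i / (N_i + s_i)``
    and the non-zero parts are multiplicatively shrunk so the row sums to
    one.  Ratios among non-zero parts are therefore preserved exactly,
    and rows without zeros equal their plain closure.

    strength: "sqrt" for s_i = sqrt(N_i) (depth-sensitive default) or a
    fixed positive number.
    """
    counts = table.counts
    if counts.shape[1] < 2:
        raise ValueError("need at least two parts")
    totals = table.totals().to_numpy(dtype=float)
    if np.any(totals <= 0):
        bad = list(counts.index[table.totals() == 0])
        raise ValueError(f"sample(s) with all-zero counts cannot be imputed: {bad}")
    if strata is None:
        strata = table.seasons()
    strata = strata.reindex(counts.index)

    props = counts.div(counts.sum(axis=1), axis=0)
    D = counts.shape[1]
    warns: list[str] = []
    priors: dict[str, np.ndarray] = {}
    for s in strata.unique():
        if prior_proportions is not None and s in prior_proportions:
            priors[s] = closure(np.asarray(prior_proportions[s], dtype=float))
            if priors[s].size != D:
                raise ValueError(f"prior for stratum {s} has wrong length")
        else:
            sub = counts.loc[strata == s]
            priors[s], w = _stratum_prior(sub, props.loc[strata == s])
            warns.extend(f"stratum {s}: {msg}" for msg in w)

    out = np.empty((counts.shape[0], D))
    n_zeros = np.zeros(counts.shape[0], dtype=int)
    strengths = np.empty(counts.shape[0])
    for i, (sid, row) in enumerate(counts.iterrows()):
        c = row.to_numpy(dtype=float)
        N = c.sum()
        s_i = float(np.sqrt(N)) if strength == "sqrt" else float(strength)
        strengths[i] = s_i
        p = priors[strata.loc[sid]]
        zero = c == 0
        n_zeros[i] = int(zero.sum())
        x = c / N
        if not zero.any():
            out[i] = x
            continue
        repl = p[zero] * s_i / (N + s_i)
        out[i, zero] = repl
        out[i, ~zero] = x[~zero] * (1.0 - repl.sum())
        smallest_obs = x[~zero].min()
        if np.any(repl > smallest_obs):
            warns.append(
                f"sample {sid}: an imputed value exceeds the smallest observed "
                "proportion (prior may be over-strong)"
            )
    for w in warns:
        logger.warning(w)

    X = CompositionMatrix(
        pd.DataFrame(out, index=counts.index, columns=counts.columns), table.dates
    )
    if not return_report:
        return X
    report = ImputationReport(
        per_sample=pd.DataFrame(
            {
                "season": strata,
                "depth": totals.astype(int),
                "n_zeros": n_zeros,
                "strength": strengths,
            },
            index=counts.index,
        ),
        priors=pd.DataFrame(priors, index=list(counts.columns)).T,
        warnings=warns,
    )
    return X, report
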