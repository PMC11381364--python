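"""Population-level statistics: normalization, EPS calling, overlap, junction lengths.

The comparison unit throughout is the *stop-site row*: row ``s`` of a sample
counts reads whose editing stopped at ES ``s`` (row 0 = no canonical editing,
row ``n_es`` = fully edited up to the truncation limit).  Samples are
normalized to a common sequencing depth of 100 000 reads so that rows are
comparable across replicates of different library sizes.

An *exacerbated pause site* (EPS) is a stop site significantly overrepresented
in a knockdown replicate relative to the control set (BH-adjusted p < alpha),
required independently in both induced replicates with a positive effect
direction.  Because each induced replicate is a single observation compared
against a small control sample, the per-replicate test defaults to the
single-case (Crawford-Howell) one-sided t-test

    t = (x - mean_c) / (sd_c * sqrt(1 + 1/m)),   df = m - 1,

which treats the replicate as one new case drawn from the control population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .calls import JL_BIN_LABELS, SamplePopulation
from .errors import (
    EmptyPopulation,
    InvalidSets,
    TooFewControls,
    TooFewSamples,
)

DEFAULT_NORM_TOTAL = 100_000.0


def normalize_counts(
    pop: SamplePopulation, total: float = DEFAULT_NORM_TOTAL
) -> SamplePopulation:
    """Scale raw stop-site counts to a fixed total (default 100 000).

    Values stay real-valued (no rounding); the raw counts are untouched.
    """
    if pop.total_standard < 1:
        raise EmptyPopulation(
            f"sample {pop.sample_id!r} has no standard reads to normalize"
        )
    pop.stop_counts_norm = pop.stop_counts_raw * (total / pop.total_standard)
    pop.norm_total = float(total)
    return pop


# ---------------------------------------------------------------------------
# EPS calling
# ---------------------------------------------------------------------------


def single_case_t(
    x: np.ndarray, control: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Crawford-Howell one-sided (greater) t of one case vs a control sample.

    ``x`` has shape (rows,), ``control`` shape (m, rows).  Returns (t, p).
    Rows with zero control variance yield t = +/-inf (p 0 or 1) or t = 0 when
    the case equals the constant controls; callers smooth such rows first.
    """
    m = control.shape[0]
    mean_c = control.mean(axis=0)
    sd_c = control.std(axis=0, ddof=1)
    denom = sd_c * np.sqrt(1.0 + 1.0 / m)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (x - mean_c) / denom
    t = np.where((denom == 0) & (x == mean_c), 0.0, t)
    p = sps.t.sf(t, df=m - 1)
    return t, p


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


@dataclass
class EPSResult:
    """Per-stop-site EPS test results across both induced replicates."""

    stop_sites: np.ndarray  # row indices 0..n_es
    p_raw: np.ndarray  # shape (2, rows)
    p_adj: np.ndarray  # shape (2, rows)
    direction: np.ndarray  # shape (2, rows): induced minus control mean
    eps_flags: set[int]
    alpha: float
    test_strategy: str = "single_case_t_one_sided"
    adjustment: str = "benjamini_hochberg"
    induced_ids: tuple[str, ...] = ()
    control_ids: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "es": self.stop_sites,
                "p_rep1": self.p_raw[0],
                "p_rep2": self.p_raw[1],
                "padj_rep1": self.p_adj[0],
                "padj_rep2": self.p_adj[1],
                "direction_rep1": self.direction[0],
                "direction_rep2": self.direction[1],
            }
        )
        df["is_eps"] = df["es"].isin(sorted(self.eps_flags))
        return df


def _norm_matrix(pops: Sequence[SamplePopulation], total: float) -> np.ndarray:
    rows = []
    for p in pops:
        if p.stop_counts_norm is None or p.norm_total != total:
            normalize_counts(p, total)
        rows.append(p.stop_counts_norm)
    return np.vstack(rows)


def eps_call(
    induced: Sequence[SamplePopulation],
    controls: Sequence[SamplePopulation],
    alpha: float = 0.05,
    total: float = DEFAULT_NORM_TOTAL,
) -> EPSResult:
    """Call exacerbated pause sites from 2 induced vs >= 2 control samples.

    Per replicate and stop-site row: single-case one-sided t against the
    control set, BH adjustment across rows within the replicate; a row is an
    EPS iff adjusted p < alpha and the induced value exceeds the control mean
    in *both* replicates.

    Rows where the controls have zero variance are tested on add-one-smoothed
    counts (raw + 1, renormalized over an inflated total) to avoid infinite t
    statistics at sparse sites; the raw reported counts are unaffected.
    """
    if len(induced) != 2:
        raise TooFewSamples(f"need exactly 2 induced replicates, got {len(induced)}")
    if len(controls) < 2:
        raise TooFewControls(f"need >= 2 controls, got {len(controls)}")
    n_es = induced[0].n_es
    for p in list(induced) + list(controls):
        if p.n_es != n_es:
            raise TooFewSamples(
                f"sample {p.sample_id!r} has n_es {p.n_es} != {n_es}: "
                "all populations must share one template"
            )
    n_rows = n_es + 1

    ind = _norm_matrix(induced, total)  # (2, rows)
    ctl = _norm_matrix(controls, total)  # (m, rows)

    # add-one smoothing (raw counts, then renormalize) for zero-variance rows
    sd_c = ctl.std(axis=0, ddof=1)
    if np.any(sd_c == 0):
        def smoothed(p: SamplePopulation) -> np.ndarray:
            return (p.stop_counts_raw + 1) * (
                total / (p.total_standard + n_rows)
            )

        ind_s = np.vstack([smoothed(p) for p in induced])
        ctl_s = np.vstack([smoothed(p) for p in controls])
        zv = sd_c == 0
        ind = np.where(zv[None, :], ind_s, ind)
        ctl = np.where(zv[None, :], ctl_s, ctl)

    p_raw = np.empty((2, n_rows))
    p_adj = np.empty((2, n_rows))
    direction = ind - ctl.mean(axis=0)[None, :]
    for r in range(2):
        _, p = single_case_t(ind[r], ctl)
        p_raw[r] = p
        p_adj[r] = bh_adjust(p)

    sig = (p_adj < alpha) & (direction > 0)
    flags = set(np.flatnonzero(sig[0] & sig[1]).tolist())
    return EPSResult(
        stop_sites=np.arange(n_rows),
        p_raw=p_raw,
        p_adj=p_adj,
        direction=direction,
        eps_flags=flags,
        alpha=alpha,
        induced_ids=tuple(p.sample_id for p in induced),
        control_ids=tuple(p.sample_id for p in controls),
    )


# ---------------------------------------------------------------------------
# EPS-set overlap
# ---------------------------------------------------------------------------


@dataclass
class OverlapResult:
    """2x2 overlap of two EPS sets over the testable ES universe."""

    both: int
    a_only: int
    b_only: int
    neither: int
    p_value: float
    odds_ratio: float
    alternative: str = "greater"

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.both, self.a_only], [self.b_only, self.neither]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "both": [self.both],
                "a_only": [self.a_only],
                "b_only": [self.b_only],
                "neither": [self.neither],
                "p_value": [self.p_value],
                "odds_ratio": [self.odds_ratio],
                "alternative": [self.alternative],
            }
        )


def overlap_fisher(
    eps_a: set[int],
    eps_b: set[int],
    n_es_testable: int,
    alternative: str = "greater",
) -> OverlapResult:
    """Fisher's exact test of EPS-set overlap enrichment.

    The universe is the testable ESs 1..n_es_testable; the default alternative
    "greater" asks whether the two sets share more sites than chance.
    """
    a, b = set(eps_a), set(eps_b)
    universe = set(range(1, n_es_testable + 1))
    if not a <= universe or not b <= universe:
        bad = sorted((a | b) - universe)
        raise InvalidSets(
            f"ES {bad} outside testable universe 1..{n_es_testable}"
        )
    both = len(a & b)
    a_only = len(a - b)
    b_only = len(b - a)
    neither = n_es_testable - both - a_only - b_only
    odds, p = sps.fisher_exact(
        [[both, a_only], [b_only, neither]], alternative=alternative
    )
    return OverlapResult(
        both=both,
        a_only=a_only,
        b_only=b_only,
        neither=neither,
        p_value=float(p),
        odds_ratio=float(odds),
        alternative=alternative,
    )


# ---------------------------------------------------------------------------
# Junction-length analysis
# ---------------------------------------------------------------------------


def jl_bin_percentages(pop: SamplePopulation) -> pd.DataFrame:
    """Percent of each stop site's reads with JL 0 / 1-10 / 11-20 / >20.

    Stop sites without reads emit no row; each emitted row sums to 100.
    """
    totals = pop.jl_bins.sum(axis=1)
    keep = totals > 0
    pct = 100.0 * pop.jl_bins[keep] / totals[keep, None]
    df = pd.DataFrame(pct, columns=[f"pct_{b}" for b in JL_BIN_LABELS])
    df.insert(0, "es", np.flatnonzero(keep))
    df.insert(1, "n_reads", totals[keep])
    return df


def jl_compare(
    induced: Sequence[SamplePopulation],
    controls: Sequence[SamplePopulation],
    bins: Sequence[str] = ("0", ">20"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sample t-tests of per-stop-site JL-bin percentages between conditions.

    For each stop site represented in every sample and each requested bin, the
    per-sample percentages are compared by a two-sided pooled-variance
    Student's t-test (induced vs control), BH-adjusted across stop sites
    within each bin.  Returns one row per (es, bin) with the group means,
    t, p, adjusted p, significance flag and effect direction.
    """
    if len(induced) < 2 or len(controls) < 2:
        raise TooFewSamples("need >= 2 samples per condition for a t-test")
    bad = set(bins) - set(JL_BIN_LABELS)
    if bad:
        raise ValueError(f"unknown JL bins {sorted(bad)}; valid: {JL_BIN_LABELS}")

    def pct_matrix(pops: Sequence[SamplePopulation]) -> np.ndarray:
        # (samples, rows, 4); NaN where a stop site has no reads
        out = []
        for p in pops:
            totals = p.jl_bins.sum(axis=1).astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                out.append(100.0 * p.jl_bins / totals[:, None])
        return np.stack(out)

    ind = pct_matrix(induced)
    ctl = pct_matrix(controls)
    testable = ~np.isnan(ind).any(axis=(0, 2)) & ~np.isnan(ctl).any(axis=(0, 2))
    rows = np.flatnonzero(testable)

    frames = []
    for b in bins:
        bi = JL_BIN_LABELS.index(b)
        x = ind[:, rows, bi]  # (2, k)
        y = ctl[:, rows, bi]  # (m, k)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = sps.ttest_ind(x, y, axis=0, equal_var=True)
        diff = x.mean(axis=0) - y.mean(axis=0)
        # degenerate rows (zero pooled variance) yield NaN: identical groups
        # carry no evidence (p=1), constant-but-different groups are maximal
        p = np.where(np.isnan(p), np.where(diff == 0, 1.0, 0.0), p)
        padj = bh_adjust(p) if len(p) else np.array([])
        frames.append(
            pd.DataFrame(
                {
                    "es": rows,
                    "bin": b,
                    "mean_induced_pct": x.mean(axis=0),
                    "mean_control_pct": y.mean(axis=0),
                    "t": t,
                    "p": p,
                    "padj": padj,
                    "significant": padj < alpha,
                    "direction": np.where(diff > 0, "induced>control", "induced<control"),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
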