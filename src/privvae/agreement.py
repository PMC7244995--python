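"""Rater-agreement statistics for ordinal 0-4 severity ratings.

Implements the validation analysis used to check that decoded videos retain
clinical information: linearly weighted Cohen kappa (disagreements of 1, 2
and 3 categories weighted 1, 2 and 3) for intra-rater agreement (same rater,
original vs decoded condition) and inter-rater agreement (all rater pairs
within one condition), plus the mean rating difference between conditions,
the proportion of ratable cells, and the conventional interpretation bands
(<=0 chance or worse, 0-0.2 slight, 0.21-0.4 fair, 0.41-0.6 moderate,
0.61-0.8 substantial, 0.81-1 almost perfect).

"Not ratable" (NR) cells are excluded pairwise-complete: a (video, rater)
pair enters a kappa only if both compared ratings are actual grades.
A kappa with no chance-corrected information (both raters constant on the
same single category) is reported as undefined, never coerced to a number.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score

NOT_RATABLE = "NR"
CATEGORIES = (0, 1, 2, 3, 4)

_BANDS = (
    (0.0, "chance or worse"),
    (0.2, "slight"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "substantial"),
    (1.0, "almost perfect"),
)


class KappaUndefinedError(ValueError):
    """Raised when kappa is undefined (no marginal variation to correct for)."""


def interpret_kappa(k: float) -> str:
    """Map a kappa value to its conventional agreement band."""
    if not -1.0 <= k <= 1.0:
        raise ValueError(f"kappa must be in [-1, 1], got {k}")
    if k <= 0.0:
        return _BANDS[0][1]
    for upper, label in _BANDS[1:]:
        if k <= upper:
            return label
    return _BANDS[-1][1]


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    n_pairs_used: int
    weight_scheme: str = "linear"
    interpretation: str = ""

    def __post_init__(self):
        if not -1.0 - 1e-12 <= self.kappa <= 1.0 + 1e-12:
            raise ValueError(f"kappa out of [-1, 1]: {self.kappa}")
        if not self.interpretation:
            object.__setattr__(self, "interpretation", interpret_kappa(self.kappa))


def _to_float(values) -> np.ndarray:
    """Ratings sequence -> float array with NaN for not-ratable entries."""
    out = np.empty(len(values), dtype=np.float64)
    for i, v in enumerate(values):
        if v is None or (isinstance(v, str) and v.strip().upper() == NOT_RATABLE):
            out[i] = np.nan
        elif isinstance(v, float) and np.isnan(v):
            out[i] = np.nan
        else:
            f = float(v)
            if f != int(f) or int(f) not in CATEGORIES:
                raise ValueError(f"rating must be in {CATEGORIES} or NR, got {v!r}")
            out[i] = f
    return out


@dataclass
class RatingTable:
    """Videos x raters grid of ordinal grades with NR stored as NaN."""

    data: pd.DataFrame
    condition: str = "original"

    def __post_init__(self):
        df = self.data.astype(float)
        vals = df.to_numpy().ravel()
        ok = np.isnan(vals) | np.isin(vals, CATEGORIES)
        if not ok.all():
            bad = sorted(set(vals[~ok]))
            raise ValueError(f"ratings outside {CATEGORIES} u {{NR}}: {bad}")
        if df.index.duplicated().any() or df.columns.duplicated().any():
            raise ValueError("video and rater identifiers must be unique")
        self.data = df

    @classmethod
    def from_columns(cls, columns: dict, video_ids, condition: str = "original"):
        df = pd.DataFrame(
            {rater: _to_float(col) for rater, col in columns.items()},
            index=list(video_ids),
        )
        return cls(df, condition=condition)

    @property
    def video_ids(self) -> list:
        return list(self.data.index)

    @property
    def rater_ids(self) -> list:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def column(self, rater) -> np.ndarray:
        return self.data[rater].to_numpy()

    def to_long(self) -> pd.DataFrame:
        """Long form: video_id, rater_id, rating with NR spelled out."""
        long = self.data.stack(future_stack=True).reset_index()
        long.columns = ["video_id", "rater_id", "rating"]
        long["rating"] = [
            NOT_RATABLE if np.isnan(v) else str(int(v)) for v in long["rating"]
        ]
        return long


def weighted_kappa(a, b, weights: str = "linear") -> KappaResult:
    """Weighted Cohen kappa between two rating vectors.

    kappa = 1 - sum(w O) / sum(w E) with w_ij = |i - j| for linear weights,
    O the observed cross-tabulation over the 5 grade categories and E the
    chance table from the marginals' outer product.  Pairs with NR in either
    vector are excluded (pairwise-complete).
    """
    if weights not in ("linear", "quadratic"):
        raise ValueError("weights must be 'linear' or 'quadratic'")
    av, bv = _to_float(list(a)), _to_float(list(b))
    if av.size != bv.size:
        raise ValueError(f"rating vectors differ in length: {av.size} vs {bv.size}")
    usable = ~(np.isnan(av) | np.isnan(bv))
    n = int(usable.sum())
    if n < 2:
        raise ValueError(f"need >= 2 usable rating pairs after NR exclusion, got {n}")
    ai = av[usable].astype(int)
    bi = bv[usable].astype(int)
    if (ai == ai[0]).all() and (bi == bi[0]).all() and ai[0] == bi[0]:
        raise KappaUndefinedError(
            "both raters used a single identical category; "
            "chance-corrected agreement is undefined"
        )
    k = float(
        cohen_kappa_score(ai, bi, labels=list(CATEGORIES), weights=weights)
    )
    return KappaResult(kappa=k, n_pairs_used=n, weight_scheme=weights)


@dataclass
class IntraraterResult:
    per_rater: dict = field(default_factory=dict)  # rater -> KappaResult
    pooled: KappaResult | None = None
    excluded: dict = field(default_factory=dict)  # rater -> reason


def _check_aligned(original: RatingTable, decoded: RatingTable) -> None:
    miss_v = set(original.video_ids) ^ set(decoded.video_ids)
    miss_r = set(original.rater_ids) ^ set(decoded.rater_ids)
    if miss_v or miss_r:
        raise ValueError(
            f"tables are misaligned; unmatched videos: {sorted(miss_v)}, "
            f"unmatched raters: {sorted(miss_r)}"
        )


def intrarater_agreement(
    original: RatingTable, decoded: RatingTable, weights: str = "linear"
) -> IntraraterResult:
    """Per-rater and pooled kappa between original- and decoded-condition ratings.

    Raters for whom kappa cannot be computed (all NR, fewer than two usable
    pairs, or undefined) are excluded with an explicit reason; the pooled
    kappa concatenates all raters' (video, rater) pairs.
    """
    _check_aligned(original, decoded)
    dec = decoded.data.loc[original.video_ids, original.rater_ids]
    result = IntraraterResult()
    all_o: list[np.ndarray] = []
    all_d: list[np.ndarray] = []
    for rater in original.rater_ids:
        o = original.column(rater)
        d = dec[rater].to_numpy()
        all_o.append(o)
        all_d.append(d)
        try:
            result.per_rater[rater] = weighted_kappa(o, d, weights)
        except (ValueError, KappaUndefinedError) as exc:
            result.excluded[rater] = str(exc)
    result.pooled = weighted_kappa(
        np.concatenate(all_o), np.concatenate(all_d), weights
    )
    return result


@dataclass
class InterraterResult:
    pairwise: pd.DataFrame = None  # raters x raters kappa matrix (NaN diag)
    mean_kappa: float = np.nan
    excluded_pairs: dict = field(default_factory=dict)  # (a, b) -> reason

    @property
    def interpretation(self) -> str:
        return interpret_kappa(self.mean_kappa)


def interrater_agreement(table: RatingTable, weights: str = "linear") -> InterraterResult:
    """Kappa for every rater pair on shared ratable videos; summary = mean.

    Pairs with fewer than two shared usable videos (or undefined kappa) are
    flagged and excluded from the mean of pairwise kappas.
    """
    raters = table.rater_ids
    if len(raters) < 2:
        raise ValueError("inter-rater agreement needs >= 2 raters")
    mat = pd.DataFrame(np.nan, index=raters, columns=raters, dtype=float)
    result = InterraterResult(pairwise=mat)
    kappas = []
    for ra, rb in itertools.combinations(raters, 2):
        try:
            res = weighted_kappa(table.column(ra), table.column(rb), weights)
        except (ValueError, KappaUndefinedError) as exc:
            result.excluded_pairs[(ra, rb)] = str(exc)
            continue
        mat.loc[ra, rb] = mat.loc[rb, ra] = res.kappa
        kappas.append(res.kappa)
    if kappas:
        result.mean_kappa = float(np.mean(kappas))
    return result


def mean_rating_difference(original: RatingTable, decoded: RatingTable) -> float:
    """Mean of (original - decoded) over cells ratable in both conditions.

    Positive values mean the original videos were rated as more severe.
    """
    _check_aligned(original, decoded)
    o = original.data.to_numpy()
    d = decoded.data.loc[original.video_ids, original.rater_ids].to_numpy()
    usable = ~(np.isnan(o) | np.isnan(d))
    if not usable.any():
        raise ValueError("no (video, rater) pair is ratable in both conditions")
    return float(np.mean(o[usable] - d[usable]))


def ratable_proportion(table: RatingTable) -> float:
    """Fraction of cells holding an actual grade rather than NR."""
    vals = table.data.to_numpy()
    if vals.size == 0:
        raise ValueError("empty rating table")
    return float(np.mean(~np.isnan(vals)))


def plot_rating_grid(tables, path=None):
    """Videos x raters grid per condition: grade as gray shade, NR in blue.

    `tables` is a list of RatingTable (one panel per condition).  Returns the
    matplotlib figure; saves to `path` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    tables = list(tables)
    cmap = ListedColormap(["0.0", "0.3", "0.55", "0.8", "1.0", "#4477dd"])
    fig, axes = plt.subplots(
        1, len(tables), figsize=(4 * len(tables), 4), squeeze=False
    )
    for ax, table in zip(axes[0], tables):
        vals = table.data.to_numpy().copy()
        vals[np.isnan(vals)] = 5  # NR slot of the colormap
        ax.imshow(vals, cmap=cmap, vmin=0, vmax=5, aspect="auto")
        ax.set_title(table.condition)
        ax.set_xlabel("rater")
        ax.set_ylabel("video")
        ax.set_xticks(range(len(table.rater_ids)))
        ax.set_xticklabels(table.rater_ids, rotation=90, fontsize=6)
        ax.set_yticks(range(len(table.video_ids)))
        ax.set_yticklabels(table.video_ids, fontsize=6)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
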