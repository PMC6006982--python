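"""Digital re-normalization of heterogeneous feature columns.

Every feature column — continuous, discrete, binary or categorical — is
mapped onto a shared integer code range (0..C-1 with C=10 by default) so
that all features contribute comparably to downstream entropy and distance
computations.  Continuous and discrete features are discretized through a
*possibly-gapped histogram*: a piecewise-linear approximation of the
empirical distribution function whose bins may be separated by empty
intervals (gaps) wherever the data leave unusually wide holes on the real
line.  Binary and categorical features are coded by reference to an anchor
feature — the non-categorical feature they are most dependent on — or
through an explicit label-to-code override map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FEATURE_TYPES = ("continuous", "discrete", "binary", "categorical")
FEATURE_ROLES = ("response", "covariate")

DEFAULT_CODE_RANGE = 10


class DegenerateFeatureError(ValueError):
    """Raised when a feature has fewer than two observations."""


class ValueOutsideSupportError(ValueError):
    """Raised when a value falls in a histogram gap or outside its range."""


class UnknownCategoryError(KeyError):
    """Raised when a categorical label was not seen when the coding was built."""


@dataclass(frozen=True)
class FeatureSpec:
    """Declared name, data type and role (response vs covariate) of a feature."""

    name: str
    declared_type: str
    role: str

    def __post_init__(self) -> None:
        if self.declared_type not in FEATURE_TYPES:
            raise ValueError(
                f"feature {self.name!r}: declared_type must be one of "
                f"{FEATURE_TYPES}, got {self.declared_type!r}"
            )
        if self.role not in FEATURE_ROLES:
            raise ValueError(
                f"feature {self.name!r}: role must be one of {FEATURE_ROLES}, "
                f"got {self.role!r}"
            )

    @property
    def is_categorical_like(self) -> bool:
        return self.declared_type in ("binary", "categorical")


@dataclass
class RawDataMatrix:
    """An n x m table of raw observations with per-feature declarations.

    ``values`` is a pandas DataFrame indexed by subject id with one column
    per feature.  Missing entries are rejected: the method has no imputation
    step and every subject must carry every feature.
    """

    values: pd.DataFrame
    specs: list[FeatureSpec]

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in specs")
        if list(self.values.columns) != names:
            raise ValueError("specs must match DataFrame columns in order")
        if len(self.values) < 2:
            raise ValueError("need at least 2 subjects")
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()].tolist()
            raise ValueError(f"missing entries not allowed (features {bad})")

    @property
    def subject_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    def spec(self, name: str) -> FeatureSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass
class PossiblyGappedHistogram:
    """Bins, gaps, counts and integer codes for one feature.

    ``bin_edges`` is an ordered list of closed intervals ``(lo, hi)``;
    consecutive bins within a gap-free stretch share an edge, while a gap is
    an explicit empty interval separating two bins.  ``codes`` maps each bin
    (in order) to an integer on the common range; codes increase strictly
    with bin order so the encoding preserves the ordering of raw values.
    """

    bin_edges: list[tuple[float, float]]
    gaps: list[tuple[float, float]]
    counts: np.ndarray
    codes: np.ndarray
    code_range: int = DEFAULT_CODE_RANGE

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.codes = np.asarray(self.codes, dtype=int)
        if len(self.bin_edges) != len(self.counts) or len(self.counts) != len(self.codes):
            raise ValueError("bin_edges, counts and codes must align")
        los = np.array([e[0] for e in self.bin_edges])
        his = np.array([e[1] for e in self.bin_edges])
        if np.any(his < los):
            raise ValueError("malformed bin interval")
        if np.any(los[1:] < his[:-1] - 1e-12):
            raise ValueError("bins overlap or are out of order")
        if len(self.codes) > 1 and np.any(np.diff(self.codes) <= 0):
            raise ValueError("codes must increase strictly with bin order")

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges)

    def locate(self, value: float) -> int:
        """Index of the bin containing ``value``; -1 if in a gap / outside."""
        los = np.array([e[0] for e in self.bin_edges])
        idx = int(np.searchsorted(los, value, side="right")) - 1
        if idx < 0:
            return -1
        lo, hi = self.bin_edges[idx]
        return idx if lo - 1e-12 <= value <= hi + 1e-12 else -1

    def nearest_bin(self, value: float) -> int:
        """Bin whose interval is closest to ``value`` (lenient snapping)."""
        best, best_d = 0, np.inf
        for i, (lo, hi) in enumerate(self.bin_edges):
            d = 0.0 if lo <= value <= hi else min(abs(value - lo), abs(value - hi))
            if d < best_d:
                best, best_d = i, d
        return best

    def midpoints(self) -> np.ndarray:
        return np.array([(lo + hi) / 2.0 for lo, hi in self.bin_edges])

    def to_dict(self) -> dict:
        return {
            "bin_edges": [list(e) for e in self.bin_edges],
            "gaps": [list(g) for g in self.gaps],
            "counts": self.counts.tolist(),
            "codes": self.codes.tolist(),
            "code_range": self.code_range,
        }


@dataclass
class CodedMatrix:
    """The re-normalized matrix: integer codes on [0, C-1], one column per feature."""

    codes: pd.DataFrame
    specs: list[FeatureSpec]
    code_range: int = DEFAULT_CODE_RANGE

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if list(self.codes.columns) != names:
            raise ValueError("specs must match code columns in order")
        arr = self.codes.to_numpy()
        if arr.size and (arr.min() < 0 or arr.max() > self.code_range - 1):
            raise ValueError(f"codes must lie on [0, {self.code_range - 1}]")

    @property
    def subject_ids(self) -> list[str]:
        return [str(i) for i in self.codes.index]

    @property
    def feature_names(self) -> list[str]:
        return list(self.codes.columns)

    def by_role(self, role: str) -> "CodedMatrix":
        keep = [s for s in self.specs if s.role == role]
        return CodedMatrix(self.codes[[s.name for s in keep]], keep, self.code_range)

    def subset(self, names: list[str]) -> "CodedMatrix":
        keep = [self.spec(n) for n in names]
        return CodedMatrix(self.codes[names], keep, self.code_range)

    def spec(self, name: str) -> FeatureSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass
class RenormalizeConfig:
    """Knobs of the re-normalization stage.

    code_range
        Size C of the common code range; codes live on 0..C-1.
    max_bins
        Bin budget per feature (capped at ``code_range`` so codes can stay
        strictly increasing across bins).
    gap_factor
        A hole between consecutive distinct sorted values wider than
        ``gap_factor`` times the median positive spacing becomes a gap.
    tol
        Maximum vertical ECDF deviation (in probability units) tolerated by
        a single linear piece before it is split into two bins.
    min_gap_frac
        A gap must also span at least this fraction of the feature's
        occupied range; suppresses spurious tail gaps in heavy-tailed
        features.
    lenient
        Snap out-of-support values to the nearest bin instead of erroring.
    overrides
        Explicit label->code maps per categorical/binary feature.
    anchors
        Explicit anchor feature name per categorical/binary feature; when
        absent the anchor is auto-selected as the non-categorical feature
        with the lowest mutual conditional entropy against the labels.
    """

    code_range: int = DEFAULT_CODE_RANGE
    max_bins: int = DEFAULT_CODE_RANGE
    gap_factor: float = 5.0
    tol: float = 0.05
    min_gap_frac: float = 0.05
    lenient: bool = False
    overrides: dict[str, dict] = field(default_factory=dict)
    anchors: dict[str, str] = field(default_factory=dict)


def _segment_distinct(distinct: np.ndarray, gap_factor: float,
                      min_gap_frac: float = 0.05):
    """Split sorted distinct values into gap-free segments.

    A hole between consecutive distinct values becomes a gap when it is wide
    both relative to the typical spacing (> gap_factor x median positive
    spacing) and relative to the feature's occupied range
    (> min_gap_frac x range); the second condition keeps heavy-tailed
    features from fragmenting into spurious tail gaps.  Returns
    (segments, gaps) where each segment is a slice (start, stop) into
    ``distinct`` and each gap is the open interval between two segments.
    """
    spacings = np.diff(distinct)
    if spacings.size == 0:
        return [(0, 1)], []
    med = float(np.median(spacings))
    span = float(distinct[-1] - distinct[0])
    cut = (spacings > gap_factor * med) & (spacings > min_gap_frac * span)
    bounds = np.flatnonzero(cut)
    segments, gaps = [], []
    start = 0
    for b in bounds:
        segments.append((start, b + 1))
        gaps.append((float(distinct[b]), float(distinct[b + 1])))
        start = b + 1
    segments.append((start, len(distinct)))
    return segments, gaps


def _piece_deviation(distinct: np.ndarray, cum: np.ndarray, a: int, b: int):
    """Max vertical ECDF deviation of the chord over distinct[a..b] (inclusive).

    ``cum[k]`` is the ECDF (fraction of sample) at and below distinct[k].
    The chord runs from the ECDF just below the piece to the ECDF at its
    right end.  Returns (deviation, split index) with split index the
    interior distinct value of maximum deviation.
    """
    if b <= a:
        return 0.0, -1
    f_lo = cum[a - 1] if a > 0 else 0.0
    f_hi = cum[b]
    x_lo, x_hi = distinct[a], distinct[b]
    if x_hi == x_lo:
        return 0.0, -1
    xs = distinct[a:b + 1]
    line = f_lo + (xs - x_lo) / (x_hi - x_lo) * (f_hi - f_lo)
    dev = np.abs(cum[a:b + 1] - line)
    k = int(np.argmax(dev[:-1])) if len(dev) > 1 else 0
    return float(dev[k]), a + k


def build_gapped_histogram(
    values,
    max_bins: int = DEFAULT_CODE_RANGE,
    gap_factor: float = 5.0,
    tol: float = 0.05,
    min_gap_frac: float = 0.05,
    code_range: int = DEFAULT_CODE_RANGE,
) -> PossiblyGappedHistogram:
    """Build a possibly-gapped histogram approximating the ECDF of ``values``.

    Gaps are declared wherever consecutive sorted distinct values are
    separated by more than ``gap_factor`` times the median positive spacing.
    Within each gap-free segment the ECDF is fit by recursive piecewise-linear
    segmentation: the piece with the largest vertical deviation is split at
    its point of maximum deviation until every piece deviates by at most
    ``tol`` or the total number of pieces reaches ``max_bins``.  Each linear
    piece becomes one bin; bins are coded by their index rescaled onto the
    common range 0..code_range-1.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if x.size < 2:
        raise DegenerateFeatureError("degenerate feature: fewer than 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    max_bins = max(1, min(int(max_bins), code_range))

    distinct, dcounts = np.unique(x, return_counts=True)
    n = x.size
    if distinct.size == 1:
        v = float(distinct[0])
        return PossiblyGappedHistogram([(v, v)], [], np.array([n]), np.array([0]),
                                       code_range)

    cum = np.cumsum(dcounts) / n
    segments, gaps = _segment_distinct(distinct, gap_factor, min_gap_frac)

    # the bin budget bounds the number of gap-free segments: when the gap
    # rule fires more often than the budget allows, keep only the widest
    # gaps (the most prominent holes) and absorb the rest
    if len(segments) > max_bins:
        widths = [hi - lo for lo, hi in gaps]
        keep = set(np.argsort(widths)[::-1][: max_bins - 1])
        merged_segments, merged_gaps = [], []
        start = segments[0][0]
        for gi, seg in enumerate(segments[:-1]):
            if gi in keep:
                merged_segments.append((start, seg[1]))
                merged_gaps.append(gaps[gi])
                start = segments[gi + 1][0]
        merged_segments.append((start, segments[-1][1]))
        segments, gaps = merged_segments, merged_gaps

    # one initial piece per gap-free segment, then greedy worst-first splits
    pieces = [(a, b - 1) for a, b in segments]
    while len(pieces) < max_bins:
        devs = [_piece_deviation(distinct, cum, a, b) for a, b in pieces]
        worst = int(np.argmax([d for d, _ in devs]))
        dev, split = devs[worst]
        if dev <= tol or split < 0:
            break
        a, b = pieces[worst]
        if split >= b:  # cannot split past the right end
            break
        pieces[worst:worst + 1] = [(a, split), (split + 1, b)]
        pieces.sort()

    seg_of = {}
    for si, (a, b) in enumerate(segments):
        for k in range(a, b):
            seg_of[k] = si

    edges: list[tuple[float, float]] = []
    counts = []
    for a, b in pieces:
        prev_same_seg = a > 0 and seg_of[a - 1] == seg_of[a]
        next_same_seg = b + 1 < len(distinct) and seg_of[b + 1] == seg_of[b]
        lo = (distinct[a - 1] + distinct[a]) / 2.0 if prev_same_seg else float(distinct[a])
        hi = (distinct[b] + distinct[b + 1]) / 2.0 if next_same_seg else float(distinct[b])
        edges.append((lo, hi))
        counts.append(int(dcounts[a:b + 1].sum()))

    n_bins = len(edges)
    if n_bins == 1:
        codes = np.array([0])
    else:
        codes = np.floor(np.arange(n_bins) * (code_range - 1) / (n_bins - 1) + 0.5)
        codes = codes.astype(int)
    return PossiblyGappedHistogram(edges, gaps, np.array(counts), codes, code_range)


def encode_feature(values, hist: PossiblyGappedHistogram, lenient: bool = False) -> np.ndarray:
    """Map raw values to the integer codes of the bins containing them.

    Larger raw values never map to smaller codes.  A value falling in a gap
    or outside the histogram's range is an error unless ``lenient`` is set,
    in which case it snaps to the nearest bin.
    """
    x = np.asarray(values, dtype=float)
    out = np.empty(x.shape, dtype=int)
    for i, v in enumerate(np.ravel(x)):
        idx = hist.locate(v)
        if idx < 0:
            if lenient:
                idx = hist.nearest_bin(v)
            else:
                raise ValueOutsideSupportError(
                    f"value outside histogram support: {v!r}"
                )
        out.flat[i] = hist.codes[idx]
    return out


def encode_categorical_with_anchor(
    cat_values,
    anchor_codes=None,
    override: dict | None = None,
    code_range: int = DEFAULT_CODE_RANGE,
) -> tuple[np.ndarray, dict]:
    """Code a categorical feature by an explicit map or by anchor conditional means.

    With ``override`` the map is applied verbatim.  Without it, each label is
    assigned the rounded mean code of the anchor feature among subjects
    carrying that label (the anchor being a non-categorical feature already
    on the common range), so that labels similar in the anchor's terms get
    similar codes; rounding ties break toward the smaller code.

    Returns the coded vector together with the label->code map actually used.
    """
    labels = np.asarray(cat_values, dtype=object)
    if override is not None:
        mapping = dict(override)
    else:
        if anchor_codes is None:
            raise ValueError("anchor_codes required when no override is given")
        anchor = np.asarray(anchor_codes, dtype=float)
        if anchor.shape[0] != labels.shape[0]:
            raise ValueError("anchor_codes must align with cat_values")
        mapping = {}
        for lab in pd.unique(labels):
            mean = anchor[labels == lab].mean()
            # round half toward the smaller code
            mapping[lab] = int(np.ceil(mean - 0.5))
    out = np.empty(labels.shape[0], dtype=int)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            raise UnknownCategoryError(f"unknown category: {lab!r}")
        out[i] = int(mapping[lab])
    if out.size and (out.min() < 0 or out.max() > code_range - 1):
        raise ValueError("category codes fall outside the common range")
    return out, mapping


def renormalize_matrix(
    raw: RawDataMatrix,
    config: RenormalizeConfig | None = None,
) -> tuple[CodedMatrix, dict[str, PossiblyGappedHistogram]]:
    """Re-normalize every column of a raw matrix onto the common code range.

    Continuous/discrete features go through :func:`build_gapped_histogram`
    and :func:`encode_feature`; binary/categorical features go through
    :func:`encode_categorical_with_anchor`, anchored (unless overridden) on
    the coded non-categorical feature with the lowest mutual conditional
    entropy against the labels.  The whole stage is deterministic: the same
    input and config always produce the identical coded matrix.
    """
    cfg = config or RenormalizeConfig()
    coded_cols: dict[str, np.ndarray] = {}
    hists: dict[str, PossiblyGappedHistogram] = {}

    numeric_specs = [s for s in raw.specs if not s.is_categorical_like]
    cat_specs = [s for s in raw.specs if s.is_categorical_like]

    for s in numeric_specs:
        try:
            hist = build_gapped_histogram(
                raw.values[s.name].to_numpy(dtype=float),
                max_bins=cfg.max_bins, gap_factor=cfg.gap_factor,
                tol=cfg.tol, min_gap_frac=cfg.min_gap_frac,
                code_range=cfg.code_range,
            )
            coded_cols[s.name] = encode_feature(
                raw.values[s.name].to_numpy(dtype=float), hist, lenient=cfg.lenient
            )
            hists[s.name] = hist
        except Exception as exc:
            raise type(exc)(f"feature {s.name!r}: {exc}") from exc

    for s in cat_specs:
        labels = raw.values[s.name].to_numpy()
        try:
            if s.name in cfg.overrides:
                codes, _ = encode_categorical_with_anchor(
                    labels, override=cfg.overrides[s.name], code_range=cfg.code_range
                )
            else:
                anchor_name = cfg.anchors.get(s.name) or _auto_anchor(
                    labels, coded_cols, numeric_specs
                )
                if anchor_name is None:
                    codes = _rank_spread_codes(labels, cfg.code_range)
                    logger.warning(
                        "feature %r: no non-categorical anchor available; "
                        "using rank-spread label coding", s.name,
                    )
                else:
                    codes, _ = encode_categorical_with_anchor(
                        labels, anchor_codes=coded_cols[anchor_name],
                        code_range=cfg.code_range,
                    )
        except Exception as exc:
            raise type(exc)(f"feature {s.name!r}: {exc}") from exc
        coded_cols[s.name] = codes

    frame = pd.DataFrame(
        {s.name: coded_cols[s.name] for s in raw.specs}, index=raw.values.index
    )
    return CodedMatrix(frame, list(raw.specs), cfg.code_range), hists


def _auto_anchor(labels, coded_cols, numeric_specs):
    """Non-categorical feature with the lowest mutual conditional entropy vs labels."""
    from .entropy import ClusteringComposition, mutual_conditional_entropy

    if not numeric_specs:
        return None
    lab_comp = ClusteringComposition.from_labels(labels)
    best_name, best_val = None, np.inf
    for s in numeric_specs:
        comp = ClusteringComposition.from_labels(coded_cols[s.name])
        val = mutual_conditional_entropy(lab_comp, comp)
        if val < best_val:
            best_name, best_val = s.name, val
    return best_name


def _rank_spread_codes(labels, code_range: int) -> np.ndarray:
    """Fallback coding when no anchor exists: sorted labels spread over the range."""
    uniq = sorted(pd.unique(np.asarray(labels, dtype=object)), key=str)
    if len(uniq) == 1:
        mapping = {uniq[0]: 0}
    else:
        mapping = {
            lab: int(np.floor(i * (code_range - 1) / (len(uniq) - 1) + 0.5))
            for i, lab in enumerate(uniq)
        }
    return np.array([mapping[lab] for lab in labels], dtype=int)
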