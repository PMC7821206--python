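"""COI barcode analyses: K2P distances, barcoding gap, net divergence.

The distance model is Kimura's two-parameter model (K2P/K80): equal base
frequencies, one rate for transitions and one for transversions,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q),

with P and Q the proportions of sites showing a transition or transversion
difference among the sites valid for the pair. Sites where either sequence
carries a gap or an ambiguity are dropped per pair (pairwise deletion).
Saturated pairs (either logarithm argument non-positive) are undefined and
flagged as NaN rather than silently dropped.

On top of pairwise distances the module provides the per-individual
barcoding-gap statistics (maximum intraspecific vs minimum interspecific
divergence), MEGA-style net between-group mean distance
d_net = d_XY - (d_X + d_Y)/2 with a site (column) bootstrap standard error,
and single-linkage threshold clustering for reconstructing lineages from
unlabelled barcodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "Alignment",
    "SequenceRecord",
    "DistanceMatrix",
    "NetDivergenceResult",
    "k2p_distance",
    "pairwise_k2p",
    "barcoding_gap",
    "net_between_group",
    "bootstrap_se",
    "net_divergence_with_bootstrap",
    "cluster_lineages",
]

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase

VALID_ALPHABET = set("ACGTN-")


@dataclass
class SequenceRecord:
    id: str
    sequence: str
    species: str | None = None


@dataclass
class Alignment:
    """Equal-length nucleotide records over {A, C, G, T, N, -}."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if self.records:
            lengths = {len(r.sequence) for r in self.records}
            if len(lengths) > 1:
                raise ValueError(f"sequences differ in length: {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record IDs: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def length(self) -> int:
        return len(self.records[0].sequence) if self.records else 0

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def species_labels(self) -> dict[str, str | None]:
        return {r.id: r.species for r in self.records}

    def codes(self) -> np.ndarray:
        """(n, L) uint8 matrix; 0..3 = ACGT, 255 = gap/ambiguity."""
        return np.vstack(
            [_CODE[np.frombuffer(r.sequence.upper().encode(), dtype=np.uint8)]
             for r in self.records]
        )

    def subset_columns(self, columns: np.ndarray) -> "Alignment":
        mats = self.codes()[:, columns]
        rev = np.array(list("ACGT?"), dtype="U1")
        out = []
        for rec, row in zip(self.records, mats):
            seq = "".join(np.where(row == 255, "N", rev[np.minimum(row, 4)]))
            out.append(SequenceRecord(rec.id, seq, rec.species))
        return Alignment(out)


@dataclass
class DistanceMatrix:
    """Symmetric K2P distance matrix (substitutions/site); NaN = undefined."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match number of IDs")
        self.values = v

    @property
    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                if np.isnan(self.values[i, j]):
                    out.append((self.ids[i], self.ids[j]))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def _pair_counts(c1: np.ndarray, c2: np.ndarray) -> tuple[int, int, int]:
    """(valid sites, transitions, transversions) under pairwise deletion."""
    valid = (c1 != 255) & (c2 != 255)
    diff = valid & (c1 != c2)
    # codes: A=0, C=1, G=2, T=3; purines {0,2}, pyrimidines {1,3}.
    # XOR of two codes equals 2 exactly for A<->G and C<->T (transitions).
    ts = diff & ((c1 ^ c2) == 2)
    return int(valid.sum()), int(ts.sum()), int(diff.sum() - ts.sum())


def _k2p_from_counts(valid: int, ts: int, tv: int) -> float:
    if valid == 0:
        return float("nan")
    P, Q = ts / valid, tv / valid
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return float("nan")  # saturated
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


def k2p_distance(seq1: str, seq2: str) -> float:
    """K2P distance between two aligned sequences (NaN when undefined)."""
    if len(seq1) != len(seq2):
        raise ValueError(f"sequence lengths differ: {len(seq1)} vs {len(seq2)}")
    c1 = _CODE[np.frombuffer(seq1.upper().encode(), dtype=np.uint8)]
    c2 = _CODE[np.frombuffer(seq2.upper().encode(), dtype=np.uint8)]
    return _k2p_from_counts(*_pair_counts(c1, c2))


def pairwise_k2p(alignment: Alignment) -> DistanceMatrix:
    """All-pairs K2P distances; symmetric with a zero diagonal."""
    if len(alignment) < 2:
        raise ValueError("need at least two records for a distance matrix")
    codes = alignment.codes()
    n = codes.shape[0]
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _k2p_from_counts(*_pair_counts(codes[i], codes[j]))
            values[i, j] = values[j, i] = d
    return DistanceMatrix(alignment.ids, values)


def _group_indices(ids: Sequence[str], labels: Mapping[str, str]) -> dict[str, list[int]]:
    groups: dict[str, list[int]] = {}
    for idx, rid in enumerate(ids):
        if rid not in labels or labels[rid] is None:
            raise KeyError(f"no species label for record {rid!r}")
        groups.setdefault(labels[rid], []).append(idx)
    return groups


def _warn_if_undefined(matrix: DistanceMatrix, context: str) -> None:
    undef = matrix.undefined_pairs
    if undef:
        warnings.warn(
            f"{context}: {len(undef)} saturated/undefined pair(s) excluded "
            f"(first: {undef[0]})",
            RuntimeWarning,
            stacklevel=3,
        )


def barcoding_gap(matrix: DistanceMatrix, labels: Mapping[str, str]) -> pd.DataFrame:
    """Per-individual barcoding-gap statistics, in percent.

    For each individual: ``max_intra`` is the largest distance to a
    conspecific (0 for singletons), ``min_inter`` the smallest distance to
    any heterospecific, ``gap`` their difference. A positive gap means the
    individual is barcode-separable from all other species.
    """
    groups = _group_indices(matrix.ids, labels)
    if len(groups) < 2:
        raise ValueError("barcoding gap needs at least two species")
    _warn_if_undefined(matrix, "barcoding_gap")
    values = matrix.values
    species_of = np.array([labels[r] for r in matrix.ids])
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        for idx, rid in enumerate(matrix.ids):
            conspecific = species_of == species_of[idx]
            intra_mask = conspecific.copy()
            intra_mask[idx] = False
            intra = values[idx, intra_mask]
            inter = values[idx, ~conspecific]
            max_intra = float(np.nanmax(intra)) * 100.0 if intra.size else 0.0
            if np.isnan(max_intra):
                max_intra = 0.0
            min_inter = float(np.nanmin(inter)) * 100.0
            rows.append(
                {
                    "id": rid,
                    "species": species_of[idx],
                    "max_intra_pct": max_intra,
                    "min_inter_pct": min_inter,
                    "gap_pct": min_inter - max_intra,
                }
            )
    return pd.DataFrame(rows).set_index("id")


@dataclass
class NetDivergenceResult:
    species_1: str
    species_2: str
    d_between: float
    d_within_1: float
    d_within_2: float
    net: float
    bootstrap_se: float | None = None
    replicates: int | None = None
    seed: int | None = None
    flags: list[str] = field(default_factory=list)


def _mean_defined(values: np.ndarray, rows: list[int], cols: list[int],
                  within: bool) -> tuple[float, bool]:
    """Mean over the requested block, excluding NaNs; True if any excluded."""
    if within:
        pairs = [values[i, j] for k, i in enumerate(rows) for j in rows[k + 1:]]
    else:
        pairs = [values[i, j] for i in rows for j in cols]
    arr = np.array(pairs, dtype=float)
    had_nan = bool(np.isnan(arr).any())
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return float("nan"), had_nan
    return float(arr.mean()), had_nan


def net_between_group(
    matrix: DistanceMatrix,
    labels: Mapping[str, str],
    pair: tuple[str, str],
) -> NetDivergenceResult:
    """Net between-group mean distance d_XY - (d_X + d_Y)/2 for one species pair.

    Within-group means over groups with a single member are defined as 0 and
    flagged. Saturated pairs are excluded from the means with a warning.
    """
    sp1, sp2 = pair
    if sp1 == sp2:
        raise ValueError(f"species pair must be distinct, got {pair}")
    groups = _group_indices(matrix.ids, labels)
    for sp in pair:
        if sp not in groups:
            raise KeyError(f"species {sp!r} not present in labels")
    _warn_if_undefined(matrix, "net_between_group")
    g1, g2 = groups[sp1], groups[sp2]
    flags: list[str] = []
    d_between, nan_b = _mean_defined(matrix.values, g1, g2, within=False)
    within = []
    for sp, g in ((sp1, g1), (sp2, g2)):
        if len(g) < 2:
            within.append(0.0)
            flags.append(f"singleton:{sp}")
        else:
            dw, nan_w = _mean_defined(matrix.values, g, [], within=True)
            within.append(dw)
            if nan_w:
                flags.append(f"saturated-excluded-within:{sp}")
    if nan_b:
        flags.append("saturated-excluded-between")
    net = d_between - 0.5 * (within[0] + within[1])
    return NetDivergenceResult(sp1, sp2, d_between, within[0], within[1], net, flags=flags)


def _pair_site_categories(codes: np.ndarray, pairs: list[tuple[int, int]]):
    """Per-pair per-site indicator matrices (valid / transition / transversion)."""
    n_pairs, L = len(pairs), codes.shape[1]
    val = np.empty((n_pairs, L))
    ts = np.empty((n_pairs, L))
    tv = np.empty((n_pairs, L))
    for k, (i, j) in enumerate(pairs):
        c1, c2 = codes[i], codes[j]
        v = (c1 != 255) & (c2 != 255)
        diff = v & (c1 != c2)
        t = diff & ((c1 ^ c2) == 2)
        val[k] = v
        ts[k] = t
        tv[k] = diff & ~t
    return val, ts, tv


def bootstrap_se(
    alignment: Alignment,
    labels: Mapping[str, str],
    pair: tuple[str, str],
    replicates: int = 1000,
    seed: int | None = None,
) -> float:
    """Site-bootstrap standard error of the net between-group distance.

    Alignment columns are resampled with replacement; the net divergence is
    recomputed per replicate and the SE is the standard deviation of the
    replicate estimates. Replicates where a needed mean is entirely undefined
    are dropped.
    """
    if replicates < 2:
        raise ValueError(f"need at least 2 bootstrap replicates, got {replicates}")
    sp1, sp2 = pair
    groups = _group_indices(alignment.ids, labels)
    for sp in pair:
        if sp not in groups:
            raise KeyError(f"species {sp!r} not present in labels")
    g1, g2 = groups[sp1], groups[sp2]
    between = [(i, j) for i in g1 for j in g2]
    within1 = [(a, b) for k, a in enumerate(g1) for b in g1[k + 1:]]
    within2 = [(a, b) for k, a in enumerate(g2) for b in g2[k + 1:]]
    pairs = between + within1 + within2
    codes = alignment.codes()
    L = codes.shape[1]
    val, ts, tv = _pair_site_categories(codes, pairs)

    rng = np.random.default_rng(seed)
    counts = np.zeros((L, replicates))
    for r in range(replicates):
        counts[:, r] = np.bincount(rng.integers(0, L, size=L), minlength=L)

    V = val @ counts  # (n_pairs, replicates) valid-site counts
    with np.errstate(divide="ignore", invalid="ignore"):
        P = (ts @ counts) / V
        Q = (tv @ counts) / V
        w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
        d = np.where((w1 > 0) & (w2 > 0) & (V > 0),
                     -0.5 * np.log(np.where(w1 > 0, w1, 1.0))
                     - 0.25 * np.log(np.where(w2 > 0, w2, 1.0)),
                     np.nan)

    n_b, n_w1 = len(between), len(within1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        d_b = np.nanmean(d[:n_b], axis=0)
        d_1 = np.nanmean(d[n_b:n_b + n_w1], axis=0) if n_w1 else np.zeros(replicates)
        d_2 = np.nanmean(d[n_b + n_w1:], axis=0) if len(within2) else np.zeros(replicates)
    nets = d_b - 0.5 * (d_1 + d_2)
    nets = nets[~np.isnan(nets)]
    if nets.size < 2:
        raise ValueError("too few defined bootstrap replicates to estimate an SE")
    return float(np.std(nets, ddof=1))


def net_divergence_with_bootstrap(
    alignment: Alignment,
    labels: Mapping[str, str],
    pair: tuple[str, str],
    replicates: int = 1000,
    seed: int | None = None,
) -> NetDivergenceResult:
    """Point estimate plus site-bootstrap SE for one species pair."""
    result = net_between_group(pairwise_k2p(alignment), labels, pair)
    result.bootstrap_se = bootstrap_se(alignment, labels, pair, replicates, seed)
    result.replicates = replicates
    result.seed = seed
    return result


def cluster_lineages(matrix: DistanceMatrix, threshold: float = 0.05) -> list[int]:
    """Single-linkage clustering of individuals, cut at a distance threshold.

    Returns one integer label per individual (1-based), renumbered so that
    labels appear in order of first occurrence. The default 0.05 threshold
    sits inside the gap between intraspecific (<~0.05) and net interspecific
    (>~0.07) divergence for this genus.
    """
    undef = matrix.undefined_pairs
    if undef:
        raise ValueError(f"cannot cluster with undefined distances: {undef}")
    n = len(matrix.ids)
    if n == 1:
        return [1]
    condensed = squareform(matrix.values, checks=False)
    raw = fcluster(linkage(condensed, method="single"), t=threshold, criterion="distance")
    remap: dict[int, int] = {}
    labels = []
    for r in raw:
        if r not in remap:
            remap[r] = len(remap) + 1
        labels.append(remap[r])
    return labels
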