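"""The correlated evolutionary-variation statistic and its significance
machinery.

For one protein, each alignment column is summarised by a vector over the
unordered species pairs (i, j): the BLOSUM transition score of the two
residues divided by the patristic divergence time of the two species
(``theta_hat``).  The classical per-site variation is the squared deviation
of ``theta_hat`` from the column mean (:class:`SiteVariation` field ``d``).
Coevolution between a column of protein A and a column of protein B is
measured as the Pearson correlation of their per-column *signals*: the
centred, standardised ``theta_hat`` vectors with the protein-wide
phylogenetic background profile (the per-species-pair mean over all
scoreable columns) removed.  Removing the background is essential: the two
proteins share one species tree, so the raw vectors of *any* two columns
correlate strongly through the common divergence-time profile alone.

Significance is empirical and self-calibrated per protein pair: the null
distribution is the background of correlations over all scoreable column
pairs of the same two proteins, summarised by evenly spaced order
statistics.  A column pair is a hit when its correlation reaches the
``(1 - alpha)`` background quantile and a bootstrap over species pairs
keeps it above that threshold in at least ``bootstrap_threshold`` of the
resamples.  Each protein pair is screened twice (forward and reversed
roles, independent bootstrap streams); only residue pairs detected in both
runs are reported, with the larger of the two p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from coevscreen.core_io import (
    GAP_CODE,
    X_CODE,
    DistanceMatrix,
    Msa,
    nj_tree,
    protein_distance_matrix,
)
from coevscreen.msa_quality import column_stats, good_blocks
from coevscreen.pairing import PairInput
from coevscreen.rng import derive_rng
from coevscreen.substitution import score_table

__all__ = [
    "EngineConfig",
    "SiteVariation",
    "VariationSet",
    "NullDistribution",
    "ScanLog",
    "ScanResult",
    "PairAbort",
    "site_variation",
    "variation_set",
    "correlate",
    "correlation_matrix",
    "null_distribution",
    "pvalue",
    "bootstrap_support",
    "scan_pair",
    "bidirectional_scan",
    "HIT_COLUMNS",
    "BIDIRECTIONAL_COLUMNS",
]


@dataclass
class EngineConfig:
    """Tunable parameters of the coevolution statistic.

    ``alpha`` is the per-protein-pair type-I-error level that places the
    significance threshold on the background null; ``bootstrap_threshold``
    is the minimum fraction of species-pair resamples that must stay above
    the threshold; ``null_samples`` caps the number of order statistics kept
    from the background distribution (and thereby the p-value resolution);
    ``min_pair_fraction`` is the minimum fraction of usable species pairs a
    column needs to be scored; ``t_min`` (substitutions/site) guards the
    division by near-zero divergence times.
    """

    alpha: float = 0.01
    bootstrap_threshold: float = 0.6
    bootstrap_reps: int = 100
    null_samples: int = 10_000
    seed: int = 0
    min_pair_fraction: float = 0.5
    tail: str = "positive"
    t_min: float = 1e-6
    matrix: str = "BLOSUM62"
    reference_species: Optional[str] = None
    min_usable_columns: int = 10

    def validate(self) -> None:
        errors = []
        if not 0.0 < self.alpha < 1.0:
            errors.append(f"alpha={self.alpha} outside (0, 1)")
        if not 0.0 <= self.bootstrap_threshold <= 1.0:
            errors.append("bootstrap_threshold outside [0, 1]")
        if self.bootstrap_reps < 1:
            errors.append("bootstrap_reps must be >= 1")
        if self.null_samples < 100:
            errors.append("null_samples must be >= 100")
        if not 0.0 <= self.min_pair_fraction <= 1.0:
            errors.append("min_pair_fraction outside [0, 1]")
        if self.tail not in ("positive", "two_sided"):
            errors.append(f"tail={self.tail!r} not in ('positive', 'two_sided')")
        if self.t_min <= 0:
            errors.append("t_min must be positive")
        if errors:
            raise ValueError("; ".join(errors))


class PairAbort(RuntimeError):
    """A protein pair cannot be scanned (too few usable columns, etc.)."""


def pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row indices (i < j) of the n(n-1)/2 unordered sequence pairs."""
    iu = np.triu_indices(n, k=1)
    return iu[0], iu[1]


@dataclass
class SiteVariation:
    """Per-column evolutionary variation of one protein.

    ``d`` is the classical squared centred corrected transition score per
    species pair; ``signal`` is the background-corrected signed vector the
    screen correlates.  ``usable`` marks species pairs where neither residue
    is a gap/'X' and the divergence time is positive; ``site_usable`` is
    False when the column has too few usable pairs or no residue variation.
    """

    protein_id: str
    column_index: int  # trimmed, 0-based
    original_column: int  # 0-based column of the untrimmed alignment
    species: list[str]
    d: np.ndarray
    signal: np.ndarray
    usable: np.ndarray
    site_usable: bool


@dataclass
class VariationSet:
    """Variation vectors for every column of one protein (vectorised).

    Arrays ``d``, ``signal`` and ``usable`` have shape (n_columns, n_pairs);
    entries outside the usable mask are zero.  ``scoreable`` marks columns
    that enter the scan: enough usable pairs and at least one usable pair
    with differing residues (a column without substitutions carries no
    information beyond the shared tree profile).
    """

    protein_id: str
    species: list[str]
    d: np.ndarray
    signal: np.ndarray
    usable: np.ndarray
    site_usable: np.ndarray
    constant: np.ndarray
    index_map: np.ndarray  # trimmed column -> original 0-based column

    @property
    def n_columns(self) -> int:
        return self.d.shape[0]

    @property
    def scoreable(self) -> np.ndarray:
        return self.site_usable & ~self.constant

    def site(self, column: int) -> SiteVariation:
        return SiteVariation(
            protein_id=self.protein_id,
            column_index=column,
            original_column=int(self.index_map[column]),
            species=self.species,
            d=self.d[column],
            signal=self.signal[column],
            usable=self.usable[column],
            site_usable=bool(self.scoreable[column]),
        )


def variation_set(
    msa: Msa,
    times: DistanceMatrix,
    matrix: str = "BLOSUM62",
    t_min: float = 1e-6,
    min_pair_fraction: float = 0.5,
    index_map: Optional[np.ndarray] = None,
) -> VariationSet:
    """Compute variation vectors for all columns of one protein.

    For each unordered sequence pair (i, j) and column c with residues
    x_i, x_j: ``theta = blosum(x_i, x_j)``; ``theta_hat = theta /
    max(t_ij, t_min)``; ``d = (theta_hat - column mean)**2`` over usable
    pairs.  The ``signal`` field holds the centred ``theta_hat``
    standardised per column, minus the per-species-pair mean profile over
    all scoreable columns (the shared phylogenetic background).
    """
    order = [times.labels.index(sp) for sp in msa.species]
    tvals = times.values[np.ix_(order, order)]
    codes = msa.to_codes()
    n, length = codes.shape
    ii, jj = pair_indices(n)
    t = tvals[ii, jj]  # (P,)
    table = score_table(matrix)
    theta = table[codes[ii, :], codes[jj, :]].T  # (L, P)
    bad_residue = np.isin(codes, (GAP_CODE, X_CODE))
    usable = ~(bad_residue[ii, :] | bad_residue[jj, :]).T & (t > 0.0)[None, :]
    theta_hat = np.where(usable, theta / np.maximum(t, t_min)[None, :], 0.0)

    n_usable = usable.sum(axis=1)
    safe_n = np.maximum(n_usable, 1)
    mean = theta_hat.sum(axis=1) / safe_n
    centred = np.where(usable, theta_hat - mean[:, None], 0.0)
    d = centred**2
    site_usable = n_usable >= np.maximum(min_pair_fraction * t.size, 3)

    # a column is informative only if some usable pair shows a substitution
    varies = ((codes[ii, :] != codes[jj, :]).T & usable).any(axis=1)
    var = (centred**2).sum(axis=1) / safe_n
    constant = ~varies | (var <= 0.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(
            (site_usable & ~constant)[:, None] & usable,
            centred / np.sqrt(np.maximum(var, 1e-300))[:, None],
            0.0,
        )
    weight = ((site_usable & ~constant)[:, None] & usable).astype(float)
    background = (u * weight).sum(axis=0) / np.maximum(weight.sum(axis=0), 1.0)
    signal = np.where(usable, u - background[None, :], 0.0)

    if index_map is None:
        index_map = np.arange(length)
    return VariationSet(
        protein_id=msa.protein_id,
        species=list(msa.species),
        d=d,
        signal=signal,
        usable=usable,
        site_usable=site_usable,
        constant=constant,
        index_map=np.asarray(index_map),
    )


def site_variation(
    msa: Msa,
    column: int,
    times: DistanceMatrix,
    matrix: str = "BLOSUM62",
    t_min: float = 1e-6,
    min_pair_fraction: float = 0.5,
) -> SiteVariation:
    """Variation vector of a single column (see :func:`variation_set`)."""
    if not 0 <= column < msa.length:
        raise IndexError(f"column {column} outside alignment of length {msa.length}")
    vs = variation_set(msa, times, matrix, t_min, min_pair_fraction)
    return vs.site(column)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    n = x.size
    if n < 3:
        return float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    vx = float(xc @ xc)
    vy = float(yc @ yc)
    scale = max(float(np.abs(x).max(initial=0.0)), 1.0) ** 2
    scale_y = max(float(np.abs(y).max(initial=0.0)), 1.0) ** 2
    if vx <= 1e-14 * n * scale or vy <= 1e-14 * n * scale_y:
        return float("nan")
    return float((xc @ yc) / math.sqrt(vx * vy))


def correlate(
    sv_a: SiteVariation, sv_b: SiteVariation, use_signal: bool = True
) -> float:
    """Pearson correlation of two site vectors over the intersection of
    their usable masks; NaN when undefined (fewer than 3 shared usable
    pairs, or either vector constant on the intersection).

    ``use_signal=True`` correlates the background-corrected signals (what
    the scan uses); ``use_signal=False`` correlates the classical squared
    variation ``d``.
    """
    if sv_a.d.shape != sv_b.d.shape or sv_a.species != sv_b.species:
        raise ValueError("variation vectors use different species-pair indexing")
    both = sv_a.usable & sv_b.usable
    if use_signal:
        return _pearson(sv_a.signal[both], sv_b.signal[both])
    return _pearson(sv_a.d[both], sv_b.d[both])


def correlation_matrix(va: VariationSet, vb: VariationSet) -> np.ndarray:
    """All-against-all column correlations between two proteins.

    Entry (i, j) is the Pearson correlation of the signals of column i of A
    and column j of B over the intersection of their usable masks; NaN
    where undefined.  Computed with masked matrix products.
    """
    if va.species != vb.species:
        raise ValueError("variation sets use different species-pair indexing")
    ma = va.usable.astype(float)
    mb = vb.usable.astype(float)
    xa = np.where(va.usable, va.signal, 0.0)
    xb = np.where(vb.usable, vb.signal, 0.0)
    n = ma @ mb.T
    sx = xa @ mb.T
    sy = ma @ xb.T
    sxx = (xa**2) @ mb.T
    syy = ma @ (xb**2).T
    sxy = xa @ xb.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        varx = sxx - sx**2 / n
        vary = syy - sy**2 / n
        rho = cov / np.sqrt(varx * vary)
    tol = 1e-10
    undef = (
        (n < 3)
        | (varx <= tol)
        | (vary <= tol)
        | ~va.scoreable[:, None]
        | ~vb.scoreable[None, :]
    )
    rho[undef] = np.nan
    return np.clip(rho, -1.0, 1.0, out=rho)


@dataclass
class NullDistribution:
    """Background null of one protein pair: the distribution of column-pair
    correlations, kept as (at most ``null_samples``) evenly spaced order
    statistics of the full background.  Deterministic for given inputs."""

    samples: np.ndarray  # sorted ascending
    threshold: float
    alpha: float
    tail: str

    @property
    def n(self) -> int:
        return self.samples.size


def _order_statistic(sorted_samples: np.ndarray, alpha: float) -> float:
    """The (1 - alpha) quantile as an order statistic: with N samples the
    threshold is the ceil((1-alpha) * N)-th smallest value."""
    n = sorted_samples.size
    k = int(math.ceil((1.0 - alpha) * n))
    k = min(max(k, 1), n)
    return float(sorted_samples[k - 1])


def null_distribution(
    va: VariationSet,
    vb: VariationSet,
    cfg: EngineConfig,
    rho_matrix: Optional[np.ndarray] = None,
) -> NullDistribution:
    """Empirical background null for one protein pair.

    All correlations between scoreable columns of A and of B form the
    background; when there are more than ``cfg.null_samples`` of them the
    sorted background is thinned to ``null_samples`` evenly spaced order
    statistics (which preserves every quantile to resolution 1/null_samples
    and keeps the construction deterministic).  The significance threshold
    is the (1 - alpha) quantile of the kept sample — with 10,000 samples and
    alpha = 0.01, the 9,900th order statistic.
    """
    n_a = int(va.scoreable.sum())
    n_b = int(vb.scoreable.sum())
    if n_a < cfg.min_usable_columns or n_b < cfg.min_usable_columns:
        raise PairAbort(
            f"too few usable columns ({n_a} in {va.protein_id}, "
            f"{n_b} in {vb.protein_id}; need {cfg.min_usable_columns})"
        )
    if rho_matrix is None:
        rho_matrix = correlation_matrix(va, vb)
    flat = rho_matrix[np.isfinite(rho_matrix)]
    if flat.size < cfg.min_usable_columns**2 // 2:
        raise PairAbort("background distribution has too few defined correlations")
    flat = np.sort(flat)
    if flat.size > cfg.null_samples:
        # evenly spaced order statistics: k-th of K picks ceil(k*N/K)-1
        k = np.arange(1, cfg.null_samples + 1)
        idx = np.ceil(k * flat.size / cfg.null_samples).astype(int) - 1
        flat = flat[idx]
    if cfg.tail == "two_sided":
        threshold = _order_statistic(np.sort(np.abs(flat)), cfg.alpha)
    else:
        threshold = _order_statistic(flat, cfg.alpha)
    return NullDistribution(flat, threshold, cfg.alpha, cfg.tail)


def pvalue(rho_obs: float | np.ndarray, null: NullDistribution):
    """Empirical p-value: (1 + #{null >= rho}) / (N + 1) for the positive
    tail; on magnitudes for the two-sided test.  Monotone non-increasing in
    the observed correlation."""
    if null.tail == "two_sided":
        samples = np.sort(np.abs(null.samples))
        obs = np.abs(rho_obs)
    else:
        samples = null.samples
        obs = rho_obs
    count = null.n - np.searchsorted(samples, obs, side="left")
    p = (1.0 + count) / (null.n + 1.0)
    if np.isscalar(rho_obs):
        return float(p)
    return p


def _exceeds(rho, threshold: float, tail: str, strict: bool = False):
    mag = np.abs(rho) if tail == "two_sided" else rho
    return mag > threshold if strict else mag >= threshold


def bootstrap_support(
    sv_a: SiteVariation,
    sv_b: SiteVariation,
    threshold: float,
    cfg: EngineConfig,
    rng: np.random.Generator,
) -> float:
    """Fraction of species-pair resamples (with replacement) whose signal
    correlation exceeds the significance threshold."""
    both = sv_a.usable & sv_b.usable
    idx = np.flatnonzero(both)
    if idx.size < 3:
        return 0.0
    x = sv_a.signal[idx]
    y = sv_b.signal[idx]
    draws = rng.integers(0, idx.size, size=(cfg.bootstrap_reps, idx.size))
    xs = x[draws]
    ys = y[draws]
    xc = xs - xs.mean(axis=1, keepdims=True)
    yc = ys - ys.mean(axis=1, keepdims=True)
    vx = (xc**2).sum(axis=1)
    vy = (yc**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rhos = (xc * yc).sum(axis=1) / np.sqrt(vx * vy)
    ok = np.isfinite(rhos)
    hits = _exceeds(rhos[ok], threshold, cfg.tail, strict=True)
    return float(np.count_nonzero(hits)) / cfg.bootstrap_reps


@dataclass
class ScanLog:
    pair_id: str
    direction: str
    n_species: int = 0
    n_columns_a: int = 0
    n_columns_b: int = 0
    n_usable_a: int = 0
    n_usable_b: int = 0
    n_comparisons: int = 0
    threshold: float = float("nan")
    n_candidates: int = 0
    n_hits: int = 0
    aborted: bool = False
    reason: str = ""

    def as_text(self) -> str:
        return "\n".join(f"{k}: {v}" for k, v in self.__dict__.items()) + "\n"


HIT_COLUMNS = [
    "pair_id",
    "protein_a",
    "protein_b",
    "site_a",
    "ref_pos_a",
    "residue_a",
    "site_b",
    "ref_pos_b",
    "residue_b",
    "rho",
    "support",
    "p",
    "gap_frac_a",
    "gap_frac_b",
    "good_a",
    "good_b",
]

BIDIRECTIONAL_COLUMNS = [
    "pair_id",
    "protein_a",
    "protein_b",
    "site_a",
    "ref_pos_a",
    "residue_a",
    "site_b",
    "ref_pos_b",
    "residue_b",
    "rho_fwd",
    "rho_rev",
    "support_fwd",
    "support_rev",
    "p",
    "gap_frac_a",
    "gap_frac_b",
    "good_a",
    "good_b",
]


@dataclass
class ScanResult:
    hits: pd.DataFrame
    log: ScanLog
    null: Optional[NullDistribution] = None
    rho: Optional[np.ndarray] = None  # correlations over scoreable columns
    p: Optional[np.ndarray] = None
    usable_sites_a: Optional[np.ndarray] = None  # original 1-based columns
    usable_sites_b: Optional[np.ndarray] = None


def _pair_times(msa: Msa, tree) -> DistanceMatrix:
    if tree is not None:
        return tree.patristic_distances()
    return nj_tree(protein_distance_matrix(msa)).patristic_distances()


def _side_quality(msa: Msa, index_map: np.ndarray, quality):
    """Per trimmed column (gap fraction, good-block flag); taken from the
    full-alignment quality record when available, otherwise computed on the
    trimmed alignment."""
    if quality is not None:
        return quality.gap_fraction[index_map], quality.in_good_block[index_map]
    cq = good_blocks(column_stats(msa))
    return cq.gap_fraction, cq.in_good_block


def _reference_positions(msa: Msa, cfg: EngineConfig):
    """1-based ungapped positions and residues of the reference row."""
    ref = cfg.reference_species
    if ref is None or ref not in msa.species:
        ref = msa.species[0]
    seq = msa.sequence(ref)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    not_gap = arr != ord("-")
    pos = np.cumsum(not_gap)
    return np.where(not_gap, pos, 0), np.array(list(seq)), ref


def scan_pair(
    pair: PairInput,
    cfg: EngineConfig,
    stream: str = "fwd",
    keep_all: bool = False,
) -> ScanResult:
    """Score every usable column pair of one protein pair (single run).

    A hit is a column pair whose correlation reaches the null threshold and
    whose bootstrap support reaches ``cfg.bootstrap_threshold``.  With
    ``keep_all`` the full correlation and p-value matrices over scoreable
    columns are also returned.
    """
    cfg.validate()
    log = ScanLog(pair.pair_id, stream, n_species=len(pair.shared_species))
    log.n_columns_a = pair.msa_a.length
    log.n_columns_b = pair.msa_b.length
    empty = pd.DataFrame(columns=HIT_COLUMNS)
    try:
        times_a = _pair_times(pair.msa_a, pair.tree_a)
        times_b = _pair_times(pair.msa_b, pair.tree_b)
    except Exception as exc:
        log.aborted = True
        log.reason = f"tree construction failed: {exc}"
        return ScanResult(empty, log)
    va = variation_set(
        pair.msa_a, times_a, cfg.matrix, cfg.t_min, cfg.min_pair_fraction,
        pair.index_map_a,
    )
    vb = variation_set(
        pair.msa_b, times_b, cfg.matrix, cfg.t_min, cfg.min_pair_fraction,
        pair.index_map_b,
    )
    cols_a = np.flatnonzero(va.scoreable)
    cols_b = np.flatnonzero(vb.scoreable)
    log.n_usable_a = cols_a.size
    log.n_usable_b = cols_b.size
    log.n_comparisons = cols_a.size * cols_b.size
    rho_full = correlation_matrix(va, vb)
    try:
        null = null_distribution(va, vb, cfg, rho_matrix=rho_full)
    except PairAbort as exc:
        log.aborted = True
        log.reason = str(exc)
        return ScanResult(empty, log)
    log.threshold = null.threshold

    rho = rho_full[np.ix_(cols_a, cols_b)]
    finite = np.isfinite(rho)
    cand_mask = np.zeros_like(finite)
    cand_mask[finite] = _exceeds(rho[finite], null.threshold, cfg.tail)
    cand_i, cand_j = np.nonzero(cand_mask)
    log.n_candidates = cand_i.size

    gaps_a, good_a = _side_quality(pair.msa_a, pair.index_map_a, pair.quality_a)
    gaps_b, good_b = _side_quality(pair.msa_b, pair.index_map_b, pair.quality_b)
    refpos_a, refres_a, _ = _reference_positions(pair.msa_a, cfg)
    refpos_b, refres_b, _ = _reference_positions(pair.msa_b, cfg)

    records = []
    for ci, cj in zip(cand_i, cand_j):
        ca = int(cols_a[ci])
        cb = int(cols_b[cj])
        site_a = int(va.index_map[ca]) + 1
        site_b = int(vb.index_map[cb]) + 1
        rng_boot = derive_rng(cfg.seed, pair.pair_id, stream, "boot", site_a, site_b)
        support = bootstrap_support(
            va.site(ca), vb.site(cb), null.threshold, cfg, rng_boot
        )
        if support < cfg.bootstrap_threshold:
            continue
        records.append(
            {
                "pair_id": pair.pair_id,
                "protein_a": pair.protein_a,
                "protein_b": pair.protein_b,
                "site_a": site_a,
                "ref_pos_a": int(refpos_a[ca]),
                "residue_a": str(refres_a[ca]),
                "site_b": site_b,
                "ref_pos_b": int(refpos_b[cb]),
                "residue_b": str(refres_b[cb]),
                "rho": float(rho[ci, cj]),
                "support": support,
                "p": pvalue(float(rho[ci, cj]), null),
                "gap_frac_a": float(gaps_a[ca]),
                "gap_frac_b": float(gaps_b[cb]),
                "good_a": bool(good_a[ca]),
                "good_b": bool(good_b[cb]),
            }
        )
    hits = pd.DataFrame(records, columns=HIT_COLUMNS)
    hits = hits.sort_values(["site_a", "site_b"], kind="mergesort").reset_index(
        drop=True
    )
    log.n_hits = len(hits)
    result = ScanResult(hits, log, null=null)
    if keep_all:
        result.rho = rho
        p = np.full(rho.shape, np.nan)
        p[finite] = pvalue(rho[finite], null)
        result.p = p
        result.usable_sites_a = va.index_map[cols_a] + 1
        result.usable_sites_b = vb.index_map[cols_b] + 1
    return result


def bidirectional_scan(
    pair: PairInput, cfg: EngineConfig
) -> tuple[pd.DataFrame, list[ScanLog]]:
    """The double-run protocol: a forward run and — only when the forward
    run found hits — a reverse run with the protein roles swapped and an
    independent bootstrap stream.  Reported hits are the exact intersection
    on (original column A, original column B); the reported p-value of a
    surviving hit is the larger of its two run p-values."""
    fwd = scan_pair(pair, cfg, stream="fwd")
    empty = pd.DataFrame(columns=BIDIRECTIONAL_COLUMNS)
    if fwd.log.aborted or fwd.hits.empty:
        return empty, [fwd.log]
    rev = scan_pair(pair.swapped(), cfg, stream="rev")
    if rev.log.aborted or rev.hits.empty:
        return empty, [fwd.log, rev.log]
    rev_hits = rev.hits.rename(
        columns={
            "site_a": "site_b",
            "site_b": "site_a",
            "ref_pos_a": "ref_pos_b",
            "ref_pos_b": "ref_pos_a",
            "residue_a": "residue_b",
            "residue_b": "residue_a",
            "gap_frac_a": "gap_frac_b",
            "gap_frac_b": "gap_frac_a",
            "good_a": "good_b",
            "good_b": "good_a",
        }
    )
    merged = fwd.hits.merge(
        rev_hits[["site_a", "site_b", "rho", "support", "p"]],
        on=["site_a", "site_b"],
        suffixes=("_fwd", "_rev"),
    )
    merged["p"] = merged[["p_fwd", "p_rev"]].max(axis=1)
    out = merged[BIDIRECTIONAL_COLUMNS].copy()
    out = out.sort_values(["site_a", "site_b"], kind="mergesort").reset_index(
        drop=True
    )
    return out, [fwd.log, rev.log]
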