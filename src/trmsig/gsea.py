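"""Gene set enrichment analysis: Signal2Noise ranking, weighted running-sum
enrichment score, permutation null, NES and FDR q.

This is a from-scratch implementation of the classic two-phenotype GSEA
procedure.  Genes are ranked by the Signal2Noise metric
r_g = (mu_A - mu_B) / (sigma_A + sigma_B) (with the customary standard
deviation floors), the enrichment score of a set is the signed maximum
deviation of the weighted hit / miss running sum over the ranked list, and
significance comes from a permutation null — either phenotype-label
permutations (exhaustively enumerated when the design admits only a few
distinct splits) or random gene sets of matched size.  NES rescales ES by
the mean same-sign null ES, and the FDR q-value follows the pooled-NES
procedure with a monotonisation over thresholds.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, StageError
from .expression import ExpressionMatrix, SampleDesign

#: minimum members (after restriction to the ranked universe) to test a set
DEFAULT_MIN_SIZE = 15

#: the standard GSEA significance rule
NOMINAL_P_CUTOFF = 0.05
FDR_Q_CUTOFF = 0.25


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ConfigurationError(f"gene set {self.name!r} has duplicate members")


@dataclass(frozen=True)
class RankedList:
    """Genes ordered by metric, descending; ties broken by gene id."""

    genes: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ConfigurationError("ranked list contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def positions(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}


def rank_genes(metric: pd.Series) -> RankedList:
    """Order genes by descending metric; lexicographic gene-id tie-break."""
    genes = metric.index.to_numpy(dtype=object)
    scores = metric.to_numpy(dtype=float)
    order = np.lexsort((genes, -scores))
    return RankedList(genes=genes[order], scores=scores[order])


def _s2n(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Signal2Noise over rows of two samples-in-columns arrays."""
    mu_a = xa.mean(axis=1)
    mu_b = xb.mean(axis=1)
    sd_a = xa.std(axis=1, ddof=1)
    sd_b = xb.std(axis=1, ddof=1)
    # floor each sd at max(0.2 * |mean|, 0.2) as in the reference tool
    sd_a = np.maximum(sd_a, np.maximum(0.2 * np.abs(mu_a), 0.2))
    sd_b = np.maximum(sd_b, np.maximum(0.2 * np.abs(mu_b), 0.2))
    return (mu_a - mu_b) / (sd_a + sd_b)


def signal_to_noise(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    group_a,
    group_b,
) -> pd.Series:
    """Per-gene Signal2Noise metric between two condition groups."""
    if matrix.scale not in ("log2", "standardised"):
        raise ConfigurationError("signal_to_noise expects log2 or standardised values")
    design.validate_against(matrix)
    a = design.samples_for(group_a)
    b = design.samples_for(group_b)
    if len(a) < 2 or len(b) < 2:
        raise ConfigurationError("each phenotype group needs >= 2 samples")
    values = _s2n(
        matrix.data[a].to_numpy(dtype=float), matrix.data[b].to_numpy(dtype=float)
    )
    return pd.Series(values, index=matrix.genes, name="signal2noise")


@dataclass(frozen=True)
class EnrichmentProfile:
    es: float
    running: np.ndarray  # deviation P_hit - P_miss at every rank
    hit_ranks: np.ndarray
    leading_edge: tuple[str, ...]
    degenerate: bool = False  # all member weights were zero


def enrichment_score(
    ranked: RankedList, gene_set: GeneSet, weight: float = 1.0
) -> EnrichmentProfile:
    """Weighted Kolmogorov-Smirnov-like running-sum enrichment score.

    P_hit accumulates |r_g|^weight over set members, P_miss accumulates
    uniformly over non-members; ES is the signed extremum of their
    difference.  The leading edge comprises members at or before the
    extremum (after it, for negative ES).
    """
    members = set(gene_set.genes) & set(ranked.genes)
    n = len(ranked)
    nh = len(members)
    if nh == 0:
        raise ConfigurationError(f"gene set {gene_set.name!r} has no genes in the ranked list")
    if nh == n:
        raise ConfigurationError(
            f"gene set {gene_set.name!r} equals the ranked universe; P_miss undefined"
        )
    hit = np.isin(ranked.genes, list(members))
    w = np.where(hit, np.abs(ranked.scores) ** weight, 0.0)
    nr = w.sum()
    if nr == 0:
        warnings.warn(
            f"gene set {gene_set.name!r}: all member metrics are zero; ES set to 0",
            stacklevel=2,
        )
        running = -np.cumsum(~hit) / (n - nh)
        return EnrichmentProfile(
            es=0.0,
            running=running,
            hit_ranks=np.flatnonzero(hit),
            leading_edge=(),
            degenerate=True,
        )
    p_hit = np.cumsum(w) / nr
    p_miss = np.cumsum(~hit) / (n - nh)
    running = p_hit - p_miss
    extremum = int(np.argmax(np.abs(running)))
    es = float(running[extremum])
    hit_ranks = np.flatnonzero(hit)
    if es >= 0:
        edge = hit_ranks[hit_ranks <= extremum]
    else:
        edge = hit_ranks[hit_ranks > extremum]
    return EnrichmentProfile(
        es=es,
        running=running,
        hit_ranks=hit_ranks,
        leading_edge=tuple(ranked.genes[edge]),
    )


def _es_from_positions(positions: np.ndarray, weights: np.ndarray, n: int) -> float:
    """ES evaluated only at hit boundaries (identical to the full profile).

    ``positions`` are sorted 0-based ranks of the set members, ``weights``
    their |r|^p values.  Between consecutive hits the running sum decays
    linearly, so its extrema occur at a rank carrying a hit or at the rank
    just before one; evaluating the deviation there reproduces the full
    cumulative-sum profile's signed extremum (first occurrence on ties).
    """
    nh = len(positions)
    nm = n - nh
    if nm == 0:
        raise ConfigurationError("gene set equals the ranked universe; P_miss undefined")
    cw = np.cumsum(weights)
    nr = cw[-1]
    if nr == 0:
        return 0.0
    i = np.arange(nh)
    after = cw / nr - (positions - i) / nm
    before = np.concatenate(([0.0], cw[:-1])) / nr - (positions - i) / nm
    cand = np.empty(2 * nh)
    cand[0::2] = before
    cand[1::2] = after
    return float(cand[np.argmax(np.abs(cand))])


def distinct_phenotype_splits(n_a: int, n_b: int) -> int:
    """Distinct unordered relabellings of an (n_a, n_b) two-group design."""
    total = math.comb(n_a + n_b, n_a)
    return total // 2 if n_a == n_b else total


def _iter_assignments(n: int, n_a: int, n_perm: int, rng: np.random.Generator):
    """Yield boolean group-A masks over n pooled samples.

    Enumerates all distinct splits when there are at most ``n_perm`` of
    them (halving mirror-image splits for balanced designs), otherwise
    samples ``n_perm`` random label permutations.
    """
    n_b = n - n_a
    if distinct_phenotype_splits(n_a, n_b) <= n_perm:
        for combo in itertools.combinations(range(n), n_a):
            if n_a == n_b and 0 not in combo:
                continue  # mirror split already yielded
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            yield mask
    else:
        for _ in range(n_perm):
            perm = rng.permutation(n)
            mask = np.zeros(n, dtype=bool)
            mask[perm[:n_a]] = True
            yield mask


def permutation_null(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    sets: list[GeneSet],
    group_a,
    group_b,
    mode: str = "gene_set",
    n_perm: int = 1000,
    seed: int | None = None,
    weight: float = 1.0,
) -> dict[str, np.ndarray]:
    """Null ES distributions per gene set.

    ``phenotype`` mode shuffles the sample labels (preserving group sizes)
    and recomputes metric and ES; with few samples the distinct splits are
    enumerated exhaustively.  ``gene_set`` mode keeps the observed ranking
    and scores random member sets of matched size; sets of equal size share
    one null pool.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    if seed is None:
        raise ConfigurationError("a seed is required for a reproducible null")
    rng = np.random.default_rng(seed)
    a = design.samples_for(group_a)
    b = design.samples_for(group_b)
    metric = signal_to_noise(matrix, design, group_a, group_b)
    ranked = rank_genes(metric)
    n = len(ranked)
    restricted = {
        s.name: np.array(sorted(set(s.genes) & set(ranked.genes)), dtype=object)
        for s in sets
    }

    if mode == "gene_set":
        absw = np.abs(ranked.scores) ** weight
        sizes = sorted({len(v) for v in restricted.values()})
        null_by_size: dict[int, np.ndarray] = {}
        for size in sizes:
            vals = np.empty(n_perm)
            for i in range(n_perm):
                pos = np.sort(rng.choice(n, size=size, replace=False))
                vals[i] = _es_from_positions(pos, absw[pos], n)
            null_by_size[size] = vals
        return {name: null_by_size[len(v)] for name, v in restricted.items()}

    if mode != "phenotype":
        raise ConfigurationError("mode must be 'phenotype' or 'gene_set'")

    n_a, n_b = len(a), len(b)
    n_splits = distinct_phenotype_splits(n_a, n_b)
    if n_splits < 10:
        raise ConfigurationError(
            f"only {n_splits} distinct phenotype splits; use mode='gene_set'"
        )
    pooled = matrix.data[a + b].to_numpy(dtype=float)
    genes = matrix.genes.to_numpy(dtype=object)
    gene_rows = {g: i for i, g in enumerate(genes)}
    member_rows = {
        name: np.array([gene_rows[g] for g in v], dtype=int)
        for name, v in restricted.items()
    }
    nulls = {name: [] for name in restricted}
    for mask in _iter_assignments(n_a + n_b, n_a, n_perm, rng):
        r = _s2n(pooled[:, mask], pooled[:, ~mask])
        order = np.lexsort((genes, -r))
        inv = np.empty(n, dtype=int)
        inv[order] = np.arange(n)
        absw = np.abs(r[order]) ** weight
        for name, rows in member_rows.items():
            pos = np.sort(inv[rows])
            nulls[name].append(_es_from_positions(pos, absw[pos], n))
    return {name: np.asarray(v) for name, v in nulls.items()}


@dataclass(frozen=True)
class GseaResult:
    """Per-set GSEA statistics plus sets excluded before testing."""

    table: pd.DataFrame  # index set name: size, es, nes, pvalue, fdr_q, significant
    excluded: dict[str, str] = field(default_factory=dict)
    leading_edges: dict[str, tuple[str, ...]] = field(default_factory=dict)
    flagged: tuple[str, ...] = ()  # sets with an undefined NES / P


def nominal_p_and_fdr(
    observed: dict[str, float],
    nulls: dict[str, np.ndarray],
    leading_edges: dict[str, tuple[str, ...]] | None = None,
    sizes: dict[str, int] | None = None,
) -> GseaResult:
    """Nominal P (side-matched, add-one), NES and pooled-NES FDR q.

    For each set the nominal P is the add-one tail frequency among
    same-sign null ES values, and NES = ES / mean(|same-sign null ES|).
    The q-value compares the pooled null NES tail fraction with the
    observed NES tail fraction at each set's NES (capped at 1) and is then
    monotonised so that a stronger NES never has a larger q.
    """
    names = list(observed)
    es = np.array([observed[n] for n in names], dtype=float)
    nes = np.full(len(names), np.nan)
    pval = np.full(len(names), np.nan)
    flagged = []
    pooled_null_nes: list[np.ndarray] = []
    for i, name in enumerate(names):
        null = np.asarray(nulls[name], dtype=float)
        pos = null[null >= 0]
        neg = null[null < 0]
        # normalise the whole null of this set for the pooled-NES FDR
        scaled = np.concatenate(
            [
                pos / pos.mean() if len(pos) and pos.mean() > 0 else np.empty(0),
                neg / np.abs(neg).mean() if len(neg) else np.empty(0),
            ]
        )
        pooled_null_nes.append(scaled)
        same = pos if es[i] >= 0 else neg
        if len(same) == 0 or np.abs(same).mean() == 0:
            flagged.append(name)
            continue
        pval[i] = (1.0 + np.sum(np.abs(same) >= abs(es[i]))) / (len(same) + 1.0)
        nes[i] = es[i] / np.abs(same).mean()
    pooled = np.concatenate(pooled_null_nes) if pooled_null_nes else np.empty(0)

    q = np.full(len(names), np.nan)
    obs_ok = ~np.isnan(nes)
    for side in (1, -1):
        side_idx = np.flatnonzero(obs_ok & ((nes >= 0) if side == 1 else (nes < 0)))
        if len(side_idx) == 0:
            continue
        null_side = pooled[pooled >= 0] if side == 1 else pooled[pooled < 0]
        n_null_side = max(len(null_side), 1)
        n_obs_side = len(side_idx)
        raw = np.empty(n_obs_side)
        for j, i in enumerate(side_idx):
            thr = abs(nes[i])
            num = np.sum(np.abs(null_side) >= thr) / n_null_side
            den = np.sum(np.abs(nes[side_idx]) >= thr) / n_obs_side
            raw[j] = min(1.0, num / den) if den > 0 else 1.0
        # q(thr) = min over more lenient thresholds of the raw FDR estimate
        order = np.argsort(np.abs(nes[side_idx]))  # ascending |NES|
        mono = np.minimum.accumulate(raw[order])
        q[side_idx[order]] = mono

    significant = (pval < NOMINAL_P_CUTOFF) & (q < FDR_Q_CUTOFF)
    sizes = sizes or {}
    table = pd.DataFrame(
        {
            "size": [sizes.get(n, np.nan) for n in names],
            "es": es,
            "nes": nes,
            "pvalue": pval,
            "fdr_q": q,
            "significant": significant,
        },
        index=pd.Index(names, name="gene_set"),
    )
    return GseaResult(
        table=table,
        leading_edges=leading_edges or {},
        flagged=tuple(flagged),
    )


def run_gsea(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    sets: list[GeneSet],
    group_a,
    group_b,
    min_size: int = DEFAULT_MIN_SIZE,
    weight: float = 1.0,
    mode: str = "gene_set",
    n_perm: int = 1000,
    seed: int | None = None,
) -> GseaResult:
    """Full GSEA: size filter, ranking, ES, permutation null, P/NES/q."""
    metric = signal_to_noise(matrix, design, group_a, group_b)
    ranked = rank_genes(metric)
    universe = set(ranked.genes)
    excluded: dict[str, str] = {}
    kept: list[GeneSet] = []
    for s in sets:
        n_in = len(set(s.genes) & universe)
        if n_in < min_size:
            excluded[s.name] = (
                f"only {n_in} members in the ranked universe; "
                f"below the minimum gene set size of {min_size}"
            )
        else:
            kept.append(s)
    if not kept:
        raise StageError("no gene set passed the minimum-size filter")
    observed: dict[str, float] = {}
    edges: dict[str, tuple[str, ...]] = {}
    sizes: dict[str, int] = {}
    for s in kept:
        profile = enrichment_score(ranked, s, weight=weight)
        observed[s.name] = profile.es
        edges[s.name] = profile.leading_edge
        sizes[s.name] = len(set(s.genes) & universe)
    nulls = permutation_null(
        matrix, design, kept, group_a, group_b,
        mode=mode, n_perm=n_perm, seed=seed, weight=weight,
    )
    result = nominal_p_and_fdr(observed, nulls, leading_edges=edges, sizes=sizes)
    return GseaResult(
        table=result.table,
        excluded=excluded,
        leading_edges=result.leading_edges,
        flagged=result.flagged,
    )
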