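"""Directional concordance of a DE result with a reference gene signature.

The signature is a list of genes each annotated ``up`` or ``down`` from a
reference contrast (here: TRM cells vs circulating memory cells).  A
signature gene counts as overlapping a DE result only when it is
significantly DE *in the same direction*.  Significance of the observed
overlap is assessed against a bootstrap null: in each of B rounds, k gene
labels and m gene labels are drawn with replacement from the expressed-gene
universe, each draw is reduced to its unique members, and the size of their
intersection forms the null overlap distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .diffexpr import DEResult
from .errors import ConfigurationError


@dataclass(frozen=True)
class DirectionalSignature:
    """Gene list with an up/down annotation per gene."""

    entries: dict[str, str]  # gene -> "up" | "down"

    def __post_init__(self) -> None:
        if not self.entries:
            raise ConfigurationError("signature must contain at least one gene")
        bad = {g: d for g, d in self.entries.items() if d not in ("up", "down")}
        if bad:
            raise ConfigurationError(f"signature directions must be up/down: {bad}")

    @property
    def k(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> list[str]:
        return list(self.entries)

    @property
    def up_count(self) -> int:
        return sum(1 for d in self.entries.values() if d == "up")


@dataclass(frozen=True)
class OverlapResult:
    """Observed directional overlap, optionally with a bootstrap P.

    ``table`` labels every signature gene ``concordant`` / ``discordant`` /
    ``not_de`` / ``not_measured``.
    """

    o_obs: int
    k: int
    m: int
    universe_size: int
    table: pd.DataFrame
    comparison_name: str = ""
    bootstraps: int | None = None
    pvalue: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.o_obs <= min(self.k, max(self.m, self.o_obs))):
            raise ValueError("observed overlap outside [0, min(k, m)]")
        if self.pvalue is not None and not (0 < self.pvalue <= 1):
            raise ValueError("bootstrap P must lie in (0, 1]")

    @property
    def percentage(self) -> float:
        """Overlap as a percentage of the signature size."""
        return 100.0 * self.o_obs / self.k

    def summary(self) -> dict[str, float]:
        counts = self.table["status"].value_counts()
        total = self.k
        return {
            "concordant_pct": 100.0 * counts.get("concordant", 0) / total,
            "discordant_pct": 100.0 * counts.get("discordant", 0) / total,
            "not_de_pct": 100.0 * counts.get("not_de", 0) / total,
            "not_measured_pct": 100.0 * counts.get("not_measured", 0) / total,
        }


def directional_overlap(signature: DirectionalSignature, de: DEResult) -> OverlapResult:
    """Count signature genes DE in the annotated direction.

    Signature genes absent from the DE universe are reported as
    ``not_measured`` (a warning, not an error: the reference signature comes
    from a different platform and need not be fully covered).
    """
    universe = de.universe
    rows = []
    for gene, wanted in signature.entries.items():
        if gene not in universe:
            rows.append((gene, wanted, "not_measured", np.nan, np.nan))
            continue
        rec = de.table.loc[gene]
        observed = rec["direction"]
        if observed == "ns":
            status = "not_de"
        elif observed == wanted:
            status = "concordant"
        else:
            status = "discordant"
        rows.append((gene, wanted, status, rec["log2fc"], rec["fdr"]))
    table = pd.DataFrame(
        rows, columns=["gene", "annotated", "status", "log2fc", "fdr"]
    ).set_index("gene")
    missing = int((table["status"] == "not_measured").sum())
    if missing:
        warnings.warn(
            f"{missing} signature gene(s) not in the tested universe", stacklevel=2
        )
    o_obs = int((table["status"] == "concordant").sum())
    return OverlapResult(
        o_obs=o_obs,
        k=signature.k,
        m=de.m,
        universe_size=len(universe),
        table=table,
        comparison_name=de.comparison.name,
    )


def _unique_intersection_counts(
    rng: np.random.Generator, n_universe: int, k: int, m: int, n_draws: int
) -> np.ndarray:
    """Null overlap sizes: |unique(k draws) & unique(m draws)| per round.

    Membership is accumulated in boolean masks, chunked to bound memory at
    roughly 25 MB regardless of B and N.
    """
    out = np.empty(n_draws, dtype=np.int64)
    chunk = max(1, min(n_draws, 25_000_000 // max(n_universe, 1)))
    done = 0
    while done < n_draws:
        b = min(chunk, n_draws - done)
        rows = np.repeat(np.arange(b), k)
        k_draw = rng.integers(0, n_universe, size=(b, k))
        mask_k = np.zeros((b, n_universe), dtype=bool)
        mask_k[rows.reshape(b, k), k_draw] = True
        rows = np.repeat(np.arange(b), m)
        m_draw = rng.integers(0, n_universe, size=(b, m))
        mask_m = np.zeros((b, n_universe), dtype=bool)
        mask_m[rows.reshape(b, m), m_draw] = True
        out[done : done + b] = (mask_k & mask_m).sum(axis=1)
        done += b
    return out


def _direction_aware_counts(
    rng: np.random.Generator,
    n_universe: int,
    k: int,
    m: int,
    p_up_sig: float,
    p_up_de: float,
    n_draws: int,
) -> np.ndarray:
    """Null concordant overlaps when draws inherit direction labels.

    Each drawn gene label carries an up/down mark (Bernoulli with the
    observed up-fractions of the signature and the DE list); only same-mark
    intersections count.
    """
    out = np.empty(n_draws, dtype=np.int64)
    chunk = max(1, min(n_draws, 12_000_000 // max(n_universe, 1)))
    done = 0
    while done < n_draws:
        b = min(chunk, n_draws - done)
        count = np.zeros(b, dtype=np.int64)
        draws = {
            "k": (k, p_up_sig),
            "m": (m, p_up_de),
        }
        masks: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for key, (size, p_up) in draws.items():
            idx = rng.integers(0, n_universe, size=(b, size))
            up = rng.random((b, size)) < p_up
            mask_up = np.zeros((b, n_universe), dtype=bool)
            mask_dn = np.zeros((b, n_universe), dtype=bool)
            rows = np.repeat(np.arange(b), size).reshape(b, size)
            mask_up[rows[up], idx[up]] = True
            mask_dn[rows[~up], idx[~up]] = True
            # a gene drawn with both marks keeps the up mark (first-class tie-break)
            mask_dn &= ~mask_up
            masks[key] = (mask_up, mask_dn)
        count += (masks["k"][0] & masks["m"][0]).sum(axis=1)
        count += (masks["k"][1] & masks["m"][1]).sum(axis=1)
        out[done : done + b] = count
        done += b
    return out


def bootstrap_enrichment(
    overlap: OverlapResult,
    universe_size: int | None = None,
    bootstraps: int = 10_000,
    seed: int | None = None,
    direction_aware: bool = False,
    p_up_signature: float | None = None,
    p_up_de: float | None = None,
) -> OverlapResult:
    """Attach a bootstrap enrichment P-value to an observed overlap.

    P = (1 + #{null overlap >= observed}) / (B + 1); the add-one term keeps
    P strictly positive, consistent with a ``< 1/B`` floor at B = 10,000.

    The default null is direction-blind (random k-set vs random m-set),
    which is conservative relative to the direction-constrained observed
    count; ``direction_aware=True`` lets the null draws inherit up/down
    marks so that only same-direction collisions count.
    """
    if bootstraps < 1:
        raise ConfigurationError("bootstraps must be >= 1")
    if seed is None:
        raise ConfigurationError("a seed is required for a reproducible bootstrap")
    n = overlap.universe_size if universe_size is None else int(universe_size)
    if n < max(overlap.k, overlap.m):
        raise ConfigurationError("universe smaller than the drawn list sizes")
    rng = np.random.default_rng(seed)
    if direction_aware:
        p_sig = (
            p_up_signature
            if p_up_signature is not None
            else float((overlap.table["annotated"] == "up").mean())
        )
        if p_up_de is None:
            de_dirs = overlap.table.loc[overlap.table["status"].isin(["concordant", "discordant"])]
            p_de = 0.5 if len(de_dirs) == 0 else float((de_dirs["annotated"] == "up").mean())
        else:
            p_de = p_up_de
        null = _direction_aware_counts(rng, n, overlap.k, overlap.m, p_sig, p_de, bootstraps)
    else:
        null = _unique_intersection_counts(rng, n, overlap.k, overlap.m, bootstraps)
    p = (1.0 + float(np.sum(null >= overlap.o_obs))) / (bootstraps + 1.0)
    return replace(overlap, universe_size=n, bootstraps=bootstraps, pvalue=p)
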