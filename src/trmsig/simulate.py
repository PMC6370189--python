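"""Synthetic FPKM data with the statistical structure of the stimulation study.

The generator emulates a 12-sample bulk RNA-seq design: four conditions
(Untreated, TGFb, IL2, IL2_TGFb) x 3 biological replicates over ~11,000
expressed genes.  The value model is additive in log2 space:

    signal_gs = baseline_g + delta_g * [TGF-beta in condition s]
                           + gamma_g * [IL-2 in condition s]
                           + Normal(0, replicate_sd)
    FPKM_gs   = max(2^signal_gs - 1, 0)

A configurable fraction of genes responds to TGF-beta (biased toward
up-regulation, as observed for TGF-beta stimulation) and an independent
fraction responds to IL-2.  Effect magnitudes are Exponential with a
0.5-log2 floor, so "responsive" is well separated from replicate noise at
n = 3.  Alongside the matrix the generator emits a machine-readable
:class:`PlantedTruth` record, a directional signature with a controlled
concordance fraction, and planted direction-consistent gene-set collections
with non-responsive negative controls — the ground truth that every
downstream recovery test checks against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .expression import (
    CONDITIONS,
    IL2_CONDITIONS,
    TGFB_CONDITIONS,
    ExpressionMatrix,
    SampleDesign,
)
from .gsea import GeneSet
from .overlap import DirectionalSignature

#: minimum gene set size accepted by the enrichment stage
MIN_SET_SIZE = 15

# rng stream tags so each artefact has its own reproducible stream
_STREAM_MATRIX = 0
_STREAM_SIGNATURE = 1
_STREAM_SETS = 2


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study; defaults emulate the real design."""

    n_genes: int = 11_000
    n_replicates: int = 3
    baseline_mean: float = 3.0  # log2-FPKM units
    baseline_sd: float = 1.5
    replicate_sd: float = 0.35
    frac_tgfb_responsive: float = 0.08
    frac_up_among_responsive: float = 0.6
    effect_size_mean: float = 1.5  # |log2FC| above the floor
    effect_floor: float = 0.5
    frac_il2_responsive: float = 0.08
    signature_size: int = 35
    signature_concordance: float = 0.6
    signature_up_count: int = 30
    n_planted_sets: int = 10
    set_size: int = 50
    n_control_sets: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_replicates <= 0:
            raise ConfigurationError("n_genes and n_replicates must be positive")
        for name in (
            "frac_tgfb_responsive",
            "frac_up_among_responsive",
            "frac_il2_responsive",
            "signature_concordance",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.signature_up_count > self.signature_size:
            raise ConfigurationError("signature_up_count exceeds signature_size")
        if self.signature_size > self.n_genes:
            raise ConfigurationError("signature_size exceeds n_genes")
        if self.set_size < MIN_SET_SIZE:
            raise ConfigurationError(
                f"set_size {self.set_size} is below the minimum gene set size "
                f"of {MIN_SET_SIZE}"
            )
        if self.replicate_sd < 0 or self.baseline_sd < 0:
            raise ConfigurationError("standard deviations must be >= 0")


@dataclass
class PlantedTruth:
    """Ground truth of a simulated dataset, JSON-serialisable."""

    genes: list[str]
    delta_tgfb: np.ndarray  # per-gene true log2FC of the TGF-beta effect
    delta_il2: np.ndarray
    signature_direction: dict[str, str] = field(default_factory=dict)
    signature_concordant: dict[str, bool] = field(default_factory=dict)
    gene_sets: dict[str, dict] = field(default_factory=dict)  # name -> {genes, direction}

    def _index(self) -> pd.Index:
        return pd.Index(self.genes)

    def responsive(self, effect: str = "tgfb") -> np.ndarray:
        delta = self.delta_tgfb if effect == "tgfb" else self.delta_il2
        return delta != 0

    def up_genes(self) -> list[str]:
        return [g for g, d in zip(self.genes, self.delta_tgfb) if d > 0]

    def down_genes(self) -> list[str]:
        return [g for g, d in zip(self.genes, self.delta_tgfb) if d < 0]

    def nonresponsive_genes(self) -> list[str]:
        return [g for g, d in zip(self.genes, self.delta_tgfb) if d == 0]

    def delta_series(self) -> pd.Series:
        return pd.Series(self.delta_tgfb, index=self._index(), name="delta_tgfb")

    def n_concordant(self) -> int:
        return sum(self.signature_concordant.values())

    def to_json(self, path) -> None:
        payload = {
            "genes": self.genes,
            "delta_tgfb": self.delta_tgfb.tolist(),
            "delta_il2": self.delta_il2.tolist(),
            "signature_direction": self.signature_direction,
            "signature_concordant": self.signature_concordant,
            "gene_sets": self.gene_sets,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["delta_tgfb"] = np.asarray(payload["delta_tgfb"])
        payload["delta_il2"] = np.asarray(payload["delta_il2"])
        return cls(**payload)


def _draw_effects(
    rng: np.random.Generator,
    n_genes: int,
    frac_responsive: float,
    frac_up: float,
    effect_mean: float,
    floor: float,
) -> np.ndarray:
    """Sparse per-gene log2 effects: Exponential magnitudes above a floor."""
    delta = np.zeros(n_genes)
    n_resp = round(frac_responsive * n_genes)
    if n_resp == 0:
        return delta
    idx = rng.choice(n_genes, size=n_resp, replace=False)
    n_up = round(frac_up * n_resp)
    magnitude = rng.exponential(scale=effect_mean, size=n_resp) + floor
    signs = np.concatenate([np.ones(n_up), -np.ones(n_resp - n_up)])
    delta[idx] = signs * magnitude
    return delta


def generate_expression_matrix(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleDesign, PlantedTruth]:
    """Simulate the FPKM matrix, the sample design and the planted truth."""
    rng = np.random.default_rng((config.seed, _STREAM_MATRIX))
    n = config.n_genes
    genes = [f"gene{i:05d}" for i in range(n)]
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    delta = _draw_effects(
        rng, n, config.frac_tgfb_responsive, config.frac_up_among_responsive,
        config.effect_size_mean, config.effect_floor,
    )
    gamma = _draw_effects(
        rng, n, config.frac_il2_responsive, 0.5,
        config.effect_size_mean, config.effect_floor,
    )

    sample_ids = []
    design_rows = []
    columns = {}
    for condition in CONDITIONS:
        for rep in range(1, config.n_replicates + 1):
            sid = f"{condition}_rep{rep}"
            sample_ids.append(sid)
            design_rows.append({"condition": condition, "replicate": rep})
            signal = baseline.copy()
            if condition in TGFB_CONDITIONS:
                signal = signal + delta
            if condition in IL2_CONDITIONS:
                signal = signal + gamma
            if config.replicate_sd > 0:
                signal = signal + rng.normal(0.0, config.replicate_sd, size=n)
            columns[sid] = np.maximum(np.exp2(signal) - 1.0, 0.0)
    matrix = ExpressionMatrix(
        data=pd.DataFrame(columns, index=pd.Index(genes, name="gene")), scale="fpkm"
    )
    design = SampleDesign(
        table=pd.DataFrame(design_rows, index=pd.Index(sample_ids, name="sample"))
    )
    truth = PlantedTruth(genes=genes, delta_tgfb=delta, delta_il2=gamma)
    return matrix, design, truth


def generate_signature(config: SimulationConfig, truth: PlantedTruth) -> DirectionalSignature:
    """Directional signature with a controlled concordance fraction.

    Concordant members are TGF-beta-responsive genes whose planted effect
    sign matches their annotation; discordant members are drawn from
    non-responsive genes.  The up/down annotation split follows
    ``signature_up_count`` and the concordant members are allocated to the
    two annotation classes in proportion.
    """
    rng = np.random.default_rng((config.seed, _STREAM_SIGNATURE))
    size = config.signature_size
    n_up = config.signature_up_count
    n_down = size - n_up
    n_conc = round(config.signature_concordance * size)
    c_up = min(round(n_conc * n_up / size), n_up) if size else 0
    c_down = n_conc - c_up
    if c_down > n_down:
        c_up += c_down - n_down
        c_down = n_down

    up_pool = truth.up_genes()
    down_pool = truth.down_genes()
    null_pool = truth.nonresponsive_genes()
    if c_up > len(up_pool) or c_down > len(down_pool):
        raise ConfigurationError(
            "not enough responsive genes for the requested concordant members; "
            "increase frac_tgfb_responsive"
        )
    if (size - n_conc) > len(null_pool):
        raise ConfigurationError("not enough non-responsive genes for discordant members")

    chosen_up = [str(g) for g in rng.choice(up_pool, size=c_up, replace=False)]
    chosen_down = [str(g) for g in rng.choice(down_pool, size=c_down, replace=False)]
    fillers = [str(g) for g in rng.choice(null_pool, size=size - n_conc, replace=False)]
    entries: dict[str, str] = {}
    concordant: dict[str, bool] = {}
    for g in chosen_up:
        entries[g] = "up"
        concordant[g] = True
    for g in fillers[: n_up - c_up]:
        entries[g] = "up"
        concordant[g] = False
    for g in chosen_down:
        entries[g] = "down"
        concordant[g] = True
    for g in fillers[n_up - c_up :]:
        entries[g] = "down"
        concordant[g] = False
    truth.signature_direction = dict(entries)
    truth.signature_concordant = concordant
    return DirectionalSignature(entries=entries)


def generate_gene_set_collection(
    config: SimulationConfig, truth: PlantedTruth
) -> list[GeneSet]:
    """Planted direction-consistent gene sets plus negative controls.

    Half the planted sets are drawn from planted-up genes, half from
    planted-down genes; controls come from genes with no TGF-beta effect.
    Individual sets may share members (they are drawn independently), which
    mirrors real tissue-specific signatures.
    """
    rng = np.random.default_rng((config.seed, _STREAM_SETS))
    n_up_sets = (config.n_planted_sets + 1) // 2
    n_down_sets = config.n_planted_sets - n_up_sets
    pools = {
        "up": truth.up_genes(),
        "down": truth.down_genes(),
        "none": truth.nonresponsive_genes(),
    }
    for direction, count in (("up", n_up_sets), ("down", n_down_sets), ("none", config.n_control_sets)):
        if count and len(pools[direction]) < config.set_size:
            raise ConfigurationError(
                f"not enough {direction}-regulated genes ({len(pools[direction])}) to fill "
                f"sets of size {config.set_size}; increase frac_tgfb_responsive"
            )
    def _draw(pool) -> tuple[str, ...]:
        return tuple(str(g) for g in rng.choice(pool, size=config.set_size, replace=False))

    sets: list[GeneSet] = []
    for i in range(n_up_sets):
        sets.append(GeneSet(f"planted_up_{i + 1}", _draw(pools["up"]), "planted up-regulated set"))
    for i in range(n_down_sets):
        sets.append(GeneSet(f"planted_down_{i + 1}", _draw(pools["down"]), "planted down-regulated set"))
    for i in range(config.n_control_sets):
        sets.append(GeneSet(f"control_{i + 1}", _draw(pools["none"]), "negative control set"))
    truth.gene_sets = {
        s.name: {
            "genes": list(s.genes),
            "direction": (
                "up" if s.name.startswith("planted_up")
                else "down" if s.name.startswith("planted_down")
                else "none"
            ),
        }
        for s in sets
    }
    return sets


def simulate_study(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleDesign, DirectionalSignature, list[GeneSet], PlantedTruth]:
    """Convenience wrapper: matrix + design + signature + gene sets + truth."""
    matrix, design, truth = generate_expression_matrix(config)
    signature = generate_signature(config, truth)
    sets = generate_gene_set_collection(config, truth)
    return matrix, design, signature, sets, truth
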