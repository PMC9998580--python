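"""Synthetic structured marker panels and quantitative traits.

The population generator follows the Balding-Nichols model: ancestral allele
frequencies are drawn uniformly on a minor-allele-frequency range, each of K
subpopulations draws its own frequency from a Beta distribution whose
concentration is governed by the divergence parameter F (an Fst analogue),
and dosages are Binomial(2, p_subpop). Raising F moves the panel from an
unstructured population to strongly separated clusters, covering the
weak / intermediate / strong structure gradient seen in real diversity
panels.

Traits are simulated with random marker effects and residuals: effects are
standard normal on the chosen effect loci, the genetic value is the centered
dosage matrix times the effects, and the residual variance is scaled from
the *realized* genetic variance so the target heritability holds in
expectation on every panel.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MarkerMatrix, write_marker_table

logger = logging.getLogger(__name__)


@dataclass
class PopSimConfig:
    n: int = 300
    m: int = 2000
    k_subpops: int = 3
    fst: float = 0.15
    maf_range: tuple[float, float] = (0.05, 0.5)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.n >= self.k_subpops >= 1:
            raise ValueError("need n >= K >= 1")
        if self.m < 1:
            raise ValueError("need at least one marker")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("MAF range must lie within (0, 0.5]")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("divergence F must lie in [0, 1)")


@dataclass
class TraitSimConfig:
    h2: float = 0.5
    n_qtl: int | str = "all"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.h2 <= 1.0:
            raise ValueError("heritability must lie in (0, 1]")


def _subpop_assignment(n: int, k: int) -> np.ndarray:
    """Split n genotypes as evenly as possible across k subpopulations."""
    base, extra = divmod(n, k)
    return np.repeat(np.arange(k), np.where(np.arange(k) < extra, base + 1, base))


def simulate_population(config: PopSimConfig) -> tuple[MarkerMatrix, np.ndarray]:
    """Generate a structured panel; returns (markers, subpopulation labels).

    Monomorphic draws are discarded and regenerated so the panel holds exactly
    ``config.m`` polymorphic markers.
    """
    rng = np.random.default_rng(config.rng_seed)
    if config.fst == 0.0 and config.k_subpops > 1:
        warnings.warn("F = 0 with K > 1 reduces to a single panmictic population")
    labels = _subpop_assignment(config.n, config.k_subpops)
    lo, hi = config.maf_range
    columns: list[np.ndarray] = []
    attempts = 0
    while len(columns) < config.m:
        batch = max(config.m - len(columns), 16)
        p_anc = rng.uniform(lo, hi, size=batch)
        if config.fst > 0:
            c = (1.0 - config.fst) / config.fst
            p_sub = rng.beta(
                p_anc[None, :] * c, (1.0 - p_anc[None, :]) * c,
                size=(config.k_subpops, batch),
            )
        else:
            p_sub = np.tile(p_anc, (config.k_subpops, 1))
        dosage = rng.binomial(2, p_sub[labels, :]).astype(float)
        poly = dosage.var(axis=0) > 0
        for j in np.nonzero(poly)[0]:
            if len(columns) < config.m:
                columns.append(dosage[:, j])
        attempts += 1
        if attempts > 1000:  # pragma: no cover
            raise RuntimeError("could not generate enough polymorphic markers")
    dosages = np.column_stack(columns)
    width = len(str(config.m))
    sample_ids = [f"G{i + 1:0{len(str(config.n))}d}" for i in range(config.n)]
    marker_ids = [f"M{j + 1:0{width}d}" for j in range(config.m)]
    return MarkerMatrix(sample_ids, marker_ids, dosages), labels


def simulate_trait(
    markers: MarkerMatrix, config: TraitSimConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate (phenotype y, true genetic value g) with target heritability.

    g = Wc beta with beta ~ N(0, 1) on the effect loci; e ~ N(0, se2) with
    se2 = var(g) (1 - h2) / h2 computed from the realized genetic variance,
    so E[var(g) / var(y)] matches the target. h2 = 1 returns y = g exactly.
    """
    rng = np.random.default_rng(config.rng_seed)
    xc = markers.centered()
    m = markers.m
    if config.n_qtl == "all":
        qtl = np.arange(m)
    else:
        n_qtl = int(config.n_qtl)
        if not 1 <= n_qtl <= m:
            raise ValueError(f"n_qtl must be in [1, {m}]")
        qtl = rng.choice(m, size=n_qtl, replace=False)
    beta = rng.normal(0.0, 1.0, size=qtl.size)
    g = xc[:, qtl] @ beta
    var_g = float(np.var(g))
    if var_g <= 0:
        raise ValueError("degenerate panel: zero genetic variance")
    if config.h2 >= 1.0:
        return g.copy(), g
    se2 = var_g * (1.0 - config.h2) / config.h2
    e = rng.normal(0.0, np.sqrt(se2), size=markers.n)
    return g + e, g


def write_fixture(
    out_dir: str,
    pop_config: PopSimConfig,
    trait_configs: list[TraitSimConfig],
    force: bool = False,
) -> dict:
    """Write a complete synthetic dataset: marker table, phenotype table
    (phenotype + true-g column per trait), subpopulation labels, and a
    manifest recording every config and seed for byte-identical replay."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty (use force=True to overwrite)")
    out.mkdir(parents=True, exist_ok=True)
    markers, labels = simulate_population(pop_config)
    write_marker_table(markers, str(out / "markers.csv"))
    pheno = {}
    for tc in trait_configs:
        y, g = simulate_trait(markers, tc)
        tag = f"trait_h{tc.h2:g}_seed{tc.rng_seed}"
        pheno[tag] = y
        pheno[f"{tag}_g"] = g
    pd.DataFrame(pheno, index=markers.sample_ids).to_csv(
        out / "phenotypes.csv", index_label="sample_id"
    )
    pd.DataFrame({"sample_id": markers.sample_ids, "subpopulation": labels}).to_csv(
        out / "labels.csv", index=False
    )
    manifest = {
        "population": asdict(pop_config),
        "traits": [asdict(tc) for tc in trait_configs],
        "files": ["markers.csv", "phenotypes.csv", "labels.csv"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("wrote fixture with %d samples, %d markers to %s", markers.n, markers.m, out)
    return manifest


def realized_heritability(y: np.ndarray, g: np.ndarray) -> float:
    """var(g) / var(y) — the realized fraction of phenotypic variance that is
    genetic for one simulated trait."""
    return float(np.var(g) / np.var(y))
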