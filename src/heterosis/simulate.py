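"""Synthetic trio datasets with known ground truth.

Emulates, at desk scale, an RNA-seq comparison of a hybrid and its two
parents in one tissue/stage: a gene-by-sample normalized expression matrix
with replicate groups for parentA, parentB and hybrid; promoter sequences
with planted AW-box motifs; and a pathway catalog with planted enrichment
among non-additive genes. Every output is reproducible bit-for-bit from the
config seed, and a TruthTable records what was planted so recovery can be
scored exactly.

Group means per gene follow a class template with geometric separation s
(default 4, comfortably above the 2-fold relation threshold), e.g. class 1
(LP < H < HP) uses LP=mu, H=s*mu, HP=s^2*mu.  Replicates are drawn
lognormally around the group mean at a given coefficient of variation —
the pipeline consumes normalized expression, so count-level noise models
are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import PathwayCatalog, PromoterSet, SampleDesign, TrioExpressionSet
from .motifs import MotifPattern, IUPAC_CODES, reverse_complement, scan_sequence

# Per-class (LP, HP, H) multipliers in units of the base mean, as functions of s.
CLASS_TEMPLATES = {
    1: lambda s: (1.0, s * s, s),      # LP < H < HP
    2: lambda s: (1.0, s, s),          # LP < H = HP
    3: lambda s: (1.0, s, 1.0),        # LP = H < HP
    4: lambda s: (1.0, 1.0, 1.0),      # LP = H = HP
    5: lambda s: (1.0, s, s * s),      # LP < HP < H
    6: lambda s: (1.0, 1.0, s),        # LP = HP < H
    7: lambda s: (s, s * s, 1.0),      # H < LP < HP
    8: lambda s: (s, s, 1.0),          # H < LP = HP
}

# Endosperm-like class shares at the key oil-synthesis stage: class 4
# (no differential expression) dominates at ~70%.
DEFAULT_CLASS_PROPORTIONS = (
    0.008, 0.136, 0.088, 0.702, 0.042, 0.005, 0.008, 0.011
)


@dataclass
class SimulationConfig:
    """Conditions for the synthetic trio, promoters and pathways."""

    n_genes: int = 800
    class_proportions: Sequence[float] = DEFAULT_CLASS_PROPORTIONS
    base_mean_range: tuple[float, float] = (5.0, 500.0)
    separation: float = 4.0          # template fold step s; must exceed fold_threshold
    noise_cv: float = 0.1            # lognormal coefficient of variation
    n_replicates: int = 3
    seed: int = 0
    tissue: str = "mesocarp"
    stage: str = "3.5MAF"
    # promoters
    n_promoters: int = 338
    motif_rate: float = 0.61
    promoter_length: int = 500
    motif: MotifPattern = field(default_factory=MotifPattern)
    clean_background: bool = True    # scrub incidental motif matches from background
    # pathways: list of (name, size, nonadditive_rate)
    pathway_spec: Sequence[tuple[str, int, float]] = ()
    fold_threshold: float = 2.0

    def __post_init__(self) -> None:
        props = np.asarray(self.class_proportions, dtype=float)
        if props.size != 8 or abs(props.sum() - 1.0) > 1e-9 or (props < 0).any():
            raise ConfigError(
                "class_proportions must be 8 non-negative values summing to 1"
            )
        if not self.separation > self.fold_threshold:
            raise ConfigError(
                f"separation {self.separation} must exceed the fold threshold "
                f"{self.fold_threshold}"
            )
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if self.n_replicates < 2:
            raise ConfigError("need >= 2 replicates per group")
        if not 0 <= self.motif_rate <= 1:
            raise ConfigError("motif_rate must be in [0, 1]")
        if len(self.motif) > self.promoter_length:
            raise ConfigError("motif longer than promoter_length")
        lo, hi = self.base_mean_range
        if not 0 < lo <= hi:
            raise ConfigError("base_mean_range must satisfy 0 < low <= high")


@dataclass
class TruthTable:
    """What the generator planted, for exact recovery scoring."""

    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    promoters: pd.DataFrame = field(default_factory=pd.DataFrame)
    pathways: pd.DataFrame = field(default_factory=pd.DataFrame)


def _lognormal_noise(rng: np.random.Generator, means: np.ndarray, cv: float) -> np.ndarray:
    """Multiplicative lognormal noise with unit mean and the given CV."""
    if cv == 0:
        return means.copy()
    sigma2 = np.log1p(cv * cv)
    sigma = np.sqrt(sigma2)
    return means * np.exp(rng.normal(-sigma2 / 2.0, sigma, size=means.shape))


def simulate_trio(cfg: SimulationConfig) -> tuple[TrioExpressionSet, TruthTable]:
    """Simulate a trio expression matrix with known per-gene class labels.

    Each gene draws a base mean mu log-uniformly from ``base_mean_range`` and
    a class from ``class_proportions``; group means follow the class template
    with separation s; which parent plays LP is a fair coin flip; replicates
    are lognormal around the group mean at ``noise_cv``.  The planted
    non-additive flag records whether the template hybrid mean differs from
    the template mid-parent value.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    lo, hi = cfg.base_mean_range
    mu = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    classes = rng.choice(np.arange(1, 9), size=n, p=np.asarray(cfg.class_proportions))
    a_is_lp = rng.random(n) < 0.5

    mean_a = np.empty(n)
    mean_b = np.empty(n)
    mean_h = np.empty(n)
    for i in range(n):
        lp, hp, h = CLASS_TEMPLATES[int(classes[i])](cfg.separation)
        lp, hp, h = lp * mu[i], hp * mu[i], h * mu[i]
        mean_a[i], mean_b[i] = (lp, hp) if a_is_lp[i] else (hp, lp)
        mean_h[i] = h
    template_mpv = (mean_a + mean_b) / 2.0
    nonadd = ~np.isclose(mean_h, template_mpv, rtol=1e-12)

    r = cfg.n_replicates
    blocks = []
    design = []
    for group, means in (
        ("parentA", mean_a), ("parentB", mean_b), ("hybrid", mean_h)
    ):
        reps = np.column_stack(
            [_lognormal_noise(rng, means, cfg.noise_cv) for _ in range(r)]
        )
        blocks.append(reps)
        design.extend(
            SampleDesign(f"{group}_r{j + 1}", group, cfg.tissue, cfg.stage)
            for j in range(r)
        )
    values = np.hstack(blocks)
    gene_ids = [f"gene{i + 1:05d}" for i in range(n)]
    xs = TrioExpressionSet(
        gene_ids=gene_ids, values=values, design=design,
        tissue=cfg.tissue, stage=cfg.stage,
    )
    truth = TruthTable(
        genes=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "class_id": classes.astype(int),
                "mean_pA": mean_a,
                "mean_pB": mean_b,
                "mean_H": mean_h,
                "nonadditive": nonadd,
            }
        )
    )
    return xs, truth


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _instantiate_motif(rng: np.random.Generator, pattern: MotifPattern) -> str:
    """Draw one concrete sequence matching the degenerate pattern."""
    return "".join(rng.choice(list(IUPAC_CODES[ch])) for ch in pattern.iupac)


def _scrub(seq: str, pattern: MotifPattern, rng: np.random.Generator) -> str:
    """Redraw windows until the sequence has no motif occurrence on any strand."""
    chars = list(seq)
    m = len(pattern)
    for _ in range(100):
        hits = scan_sequence("".join(chars), pattern)
        if not hits:
            return "".join(chars)
        for h in hits:
            chars[h.start : h.end] = rng.choice(list("ACGT"), size=m)
    raise RuntimeError("failed to scrub motif matches from background sequence")


def simulate_promoters(cfg: SimulationConfig) -> tuple[PromoterSet, TruthTable]:
    """Simulate promoters, planting one motif instance at rate ``motif_rate``.

    Planted instances instantiate every degenerate pattern position uniformly
    and sit on a random strand at a recorded position. With
    ``clean_background`` (default) the background is scrubbed of incidental
    matches so motif presence equals the planting record exactly; disable it
    to study the spurious-match rate of random sequence.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    m = len(cfg.motif)
    records: dict[str, str] = {}
    rows = []
    for i in range(cfg.n_promoters):
        gene_id = f"prom{i + 1:05d}"
        seq = _random_sequence(rng, cfg.promoter_length)
        if cfg.clean_background:
            seq = _scrub(seq, cfg.motif, rng)
        planted = bool(rng.random() < cfg.motif_rate)
        start, strand, instance = -1, ".", ""
        if planted:
            start = int(rng.integers(0, cfg.promoter_length - m + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            instance = _instantiate_motif(rng, cfg.motif)
            inserted = instance if strand == "+" else reverse_complement(instance)
            seq = seq[:start] + inserted + seq[start + m:]
        records[gene_id] = seq
        rows.append(
            {"gene_id": gene_id, "planted": planted, "start": start,
             "strand": strand, "instance": instance}
        )
    return PromoterSet(records=records), TruthTable(promoters=pd.DataFrame(rows))


def simulate_pathways(cfg: SimulationConfig, truth: TruthTable) -> PathwayCatalog:
    """Build a pathway catalog planting enrichment among non-additive genes.

    Each (name, size, nonadditive_rate) in ``cfg.pathway_spec`` samples
    ``size`` member genes without replacement, weighting planted-nonadditive
    genes by rate/n_nonadditive and the rest by (1-rate)/n_additive.  When
    the rate equals the background non-additive fraction the weights are
    uniform, so a pathway under the null is an exact uniform draw from the
    universe.
    """
    if truth.genes.empty:
        raise ConfigError("truth table has no genes; run simulate_trio first")
    rng = np.random.default_rng(cfg.seed + 2)
    genes = truth.genes["gene_id"].to_numpy()
    nonadd = truth.genes["nonadditive"].to_numpy(dtype=bool)
    n_na = int(nonadd.sum())
    n_add = int((~nonadd).sum())
    background = n_na / len(genes)

    pathways: dict[str, frozenset[str]] = {}
    rows = []
    for name, size, rate in cfg.pathway_spec:
        if size < 1 or size > len(genes):
            raise ConfigError(f"pathway {name!r}: size {size} infeasible")
        if not 0 <= rate <= 1:
            raise ConfigError(f"pathway {name!r}: rate {rate} outside [0, 1]")
        if rate > 0 and n_na == 0:
            raise ConfigError(f"pathway {name!r}: no non-additive genes to draw")
        if rate < 1 and n_add == 0:
            raise ConfigError(f"pathway {name!r}: no additive genes to draw")
        if rate == 1.0 and size > n_na:
            raise ConfigError(
                f"pathway {name!r}: size {size} exceeds the {n_na} "
                "non-additive genes available at rate 1"
            )
        if rate == 0.0 and size > n_add:
            raise ConfigError(
                f"pathway {name!r}: size {size} exceeds the {n_add} "
                "additive genes available at rate 0"
            )
        w = np.where(
            nonadd,
            rate / n_na if n_na else 0.0,
            (1.0 - rate) / n_add if n_add else 0.0,
        )
        # Gumbel top-k: weighted sampling without replacement
        with np.errstate(divide="ignore"):
            keys = np.log(w) + rng.gumbel(size=len(genes))
        members = genes[np.argsort(keys)[-size:]]
        pathways[name] = frozenset(members)
        rows.append(
            {"name": name, "size": size, "nonadditive_rate": rate,
             "enriched": rate > background}
        )
    truth.pathways = pd.DataFrame(rows)
    return PathwayCatalog(pathways=pathways, universe=frozenset(genes))
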