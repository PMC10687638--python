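"""Synthetic RNA-seq data with planted homeolog-triplet structure.

The generator emulates the experimental design every downstream stage expects:
negative-binomial gene counts (variance mu + phi * mu**2; phi = 0 is the
Poisson limit) over two conditions x a small number of replicates, genes
organized into triplets with planted presence categories (3/2/1/0 expressed
copies), planted dominance classes (Class 1 one-high, Class 2 two-high,
Class 3 all-equal, plus unstructured), and planted cold-induction patterns
(Types 1/2/3 with a controllable inducibility spread for "divergent" Type 1
triplets).  The planted truth is recorded so classifier recovery can be
scored exactly.

Key conventions:

* an *unexpressed* planted copy has mean exactly 0 (its counts are 0), so
  presence truth is unambiguous;
* expected counts are length-scaled (mean proportional to gene length, with
  lengths uniform on [500, 5000] bp) so FPKM and raw-count ranks differ;
* per-sample library factors are log-uniform on [0.7, 1.4] to exercise
  between-sample normalization;
* dominance classes and induction types are planted only on triplets with
  all three copies expressed — an unexpressed copy can neither dominate nor
  be induced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix, HomeotripError, TripletMap

LENGTH_RANGE = (500, 5000)  # bp, uniform
MEAN_LENGTH = (LENGTH_RANGE[0] + LENGTH_RANGE[1]) / 2
LIB_FACTOR_RANGE = (0.7, 1.4)  # log-uniform per-sample depth multipliers
BASE_SDLOG = 0.6  # lognormal spread of per-triplet baseline expression

# defaults mirror the observed structure of a hexaploid leaf transcriptome:
# ~76% of triplets with all three copies expressed, dominance classes at
# roughly 9/8/17% of fully-expressed triplets, ~15% of fully-expressed
# triplets with at least one cold-induced copy.
DEFAULT_CLASS_PROPORTIONS = {"class1": 0.093, "class2": 0.079, "class3": 0.165, "unstructured": 0.663}
DEFAULT_PRESENCE_PROPORTIONS = {3: 0.760, 2: 0.064, 1: 0.060, 0: 0.116}
DEFAULT_INDUCTION_PROPORTIONS = {"type1": 0.037, "type2": 0.055, "type3": 0.056, "none": 0.852}


def _check_proportions(name: str, props: dict, keys) -> None:
    if set(props) != set(keys):
        raise HomeotripError(f"{name} must have keys {sorted(map(str, keys))}")
    vals = np.array([props[k] for k in keys], dtype=float)
    if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-9:
        raise HomeotripError(f"{name} must be non-negative and sum to 1")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dataset; defaults are the reference validation conditions."""

    n_triplets: int = 2000
    n_singletons: int = 500
    replicates_per_condition: int = 2
    baseline_mean: float = 100.0  # expected count of an expressed average-length gene
    dispersion: float = 0.1  # NB phi; 0 -> Poisson
    class_proportions: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS))
    presence_proportions: dict = field(default_factory=lambda: dict(DEFAULT_PRESENCE_PROPORTIONS))
    induction_proportions: dict = field(default_factory=lambda: dict(DEFAULT_INDUCTION_PROPORTIONS))
    dominance_fc: float = 4.0  # planted high/low ratio, must be > 2
    induction_lfc: float = 2.0  # planted log2 FC of induced genes, must be > 1
    divergent_type1_fraction: float = 0.10
    singleton_induced_fraction: float = 0.15
    library_size: float | None = None  # expected reads/sample; None -> set by baseline_mean
    seed: int = 0

    def validate(self) -> None:
        for fname in ("n_triplets", "n_singletons", "replicates_per_condition"):
            if getattr(self, fname) < 0:
                raise HomeotripError(f"{fname} must be >= 0")
        if self.replicates_per_condition == 0:
            raise HomeotripError("replicates_per_condition must be >= 1")
        if self.dispersion < 0:
            raise HomeotripError("dispersion must be >= 0")
        if self.dominance_fc <= 2:
            raise HomeotripError("dominance_fc must be > 2")
        if self.induction_lfc <= 1:
            raise HomeotripError("induction_lfc must be > 1")
        if not 0 <= self.divergent_type1_fraction <= 1:
            raise HomeotripError("divergent_type1_fraction must be in [0, 1]")
        _check_proportions("class_proportions", self.class_proportions, DEFAULT_CLASS_PROPORTIONS)
        _check_proportions("presence_proportions", self.presence_proportions, DEFAULT_PRESENCE_PROPORTIONS)
        _check_proportions("induction_proportions", self.induction_proportions, DEFAULT_INDUCTION_PROPORTIONS)


@dataclass
class TruthLabels:
    """Planted truth: one row per triplet and one per gene."""

    triplets: pd.DataFrame  # anchor-indexed: presence, class, type, divergent
    genes: pd.DataFrame  # gene-indexed: anchor, expressed, control_level, true_lfc, induced


def _choice(rng: np.random.Generator, props: dict, size: int) -> np.ndarray:
    keys = list(props)
    return rng.choice(keys, size=size, p=[props[k] for k in keys])


def simulate_dataset(config: SimulationConfig) -> tuple[CountMatrix, TripletMap, pd.Series, TruthLabels]:
    """Generate (counts, triplet map, gene lengths, truth) from one config + seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    nrep = config.replicates_per_condition

    gene_rows = []  # gene, anchor, copy, expressed, control_level, true_lfc, induced
    trip_rows = []

    presence = _choice(rng, config.presence_proportions, config.n_triplets).astype(int)
    for t in range(config.n_triplets):
        anchor = f"ANCHOR{t:05d}"
        genes = [f"TRIP{t:05d}.{c}" for c in (1, 2, 3)]
        pres = int(presence[t])
        base = config.baseline_mean * float(np.exp(rng.normal(0, BASE_SDLOG) - BASE_SDLOG**2 / 2))
        expressed = np.zeros(3, dtype=bool)
        expressed[rng.choice(3, size=pres, replace=False)] = True
        levels = np.zeros(3)
        cls = "na"
        if pres == 3:
            cls = str(_choice(rng, config.class_proportions, 1)[0])
            if cls == "class1":
                hi = rng.integers(3)
                jit = 2.0 ** rng.uniform(-0.15, 0.15, 3)
                levels = base * jit
                levels[hi] = base * config.dominance_fc * float(np.max(jit)) * 1.01
            elif cls == "class2":
                lo = rng.integers(3)
                levels[:] = base * config.dominance_fc
                levels[lo] = base
            elif cls == "class3":
                levels = base * 2.0 ** rng.uniform(-0.2, 0.2, 3)
            else:
                levels = base * 2.0 ** rng.uniform(-0.9, 0.9, 3)
        else:
            levels[expressed] = base

        ttype, divergent = "na", "n/a"
        lfc = np.zeros(3)
        if pres == 3:
            ttype = str(_choice(rng, config.induction_proportions, 1)[0])
            if ttype == "type1":
                if rng.random() < config.divergent_type1_fraction:
                    divergent = "divergent"
                    lfc[:] = config.induction_lfc + rng.uniform(0, 0.25, 3)
                    lfc[rng.integers(3)] = config.induction_lfc + 1.3
                else:
                    divergent = "similar"
                    lfc[:] = config.induction_lfc + rng.uniform(0, 0.4, 3)
            elif ttype in ("type2", "type3"):
                k = 2 if ttype == "type2" else 1
                idx = rng.choice(3, size=k, replace=False)
                lfc[idx] = config.induction_lfc + rng.uniform(0, 0.4, k)
        for c in range(3):
            gene_rows.append(
                {
                    "gene": genes[c],
                    "anchor": anchor,
                    "expressed": bool(expressed[c]),
                    "control_level": float(levels[c]),
                    "true_lfc": float(lfc[c]),
                    "induced": bool(lfc[c] > 0),
                }
            )
        trip_rows.append(
            {
                "anchor": anchor,
                "copy1": genes[0],
                "copy2": genes[1],
                "copy3": genes[2],
                "presence": pres,
                "class": cls,
                "type": ttype,
                "divergent": divergent,
            }
        )

    for i in range(config.n_singletons):
        base = config.baseline_mean * float(np.exp(rng.normal(0, BASE_SDLOG) - BASE_SDLOG**2 / 2))
        induced = bool(rng.random() < config.singleton_induced_fraction)
        lfc = float(config.induction_lfc + rng.uniform(0, 0.4)) if induced else 0.0
        gene_rows.append(
            {
                "gene": f"SING{i:05d}",
                "anchor": "",
                "expressed": True,
                "control_level": base,
                "true_lfc": lfc,
                "induced": induced,
            }
        )

    genes_df = pd.DataFrame(gene_rows).set_index("gene")
    trips_df = pd.DataFrame(trip_rows).set_index("anchor") if trip_rows else pd.DataFrame(
        columns=["copy1", "copy2", "copy3", "presence", "class", "type", "divergent"]
    )
    n_genes = len(genes_df)
    lengths = pd.Series(
        rng.integers(LENGTH_RANGE[0], LENGTH_RANGE[1] + 1, n_genes), index=genes_df.index, name="length_bp"
    )

    sample_ids, conditions, replicates = [], [], []
    for cond in ("control", "cold"):
        for rep in range(1, nrep + 1):
            sample_ids.append(f"{cond}_{rep}")
            conditions.append(cond)
            replicates.append(rep)
    samples = pd.DataFrame({"condition": conditions, "replicate": replicates}, index=pd.Index(sample_ids, name="sample"))

    lib_factors = np.exp(rng.uniform(np.log(LIB_FACTOR_RANGE[0]), np.log(LIB_FACTOR_RANGE[1]), len(sample_ids)))
    level_ctrl = genes_df["control_level"].to_numpy()
    level_cold = level_ctrl * 2.0 ** genes_df["true_lfc"].to_numpy()
    len_scale = lengths.to_numpy() / MEAN_LENGTH
    mu = np.empty((n_genes, len(sample_ids)))
    for j, cond in enumerate(conditions):
        level = level_ctrl if cond == "control" else level_cold
        mu[:, j] = level * len_scale * lib_factors[j]
    if config.library_size is not None:
        col_expect = mu.mean(axis=0) * n_genes / lib_factors  # expected reads at factor 1
        scale = config.library_size / np.mean(col_expect)
        mu *= scale

    if config.dispersion > 0:
        r = 1.0 / config.dispersion
        lam = rng.gamma(r, mu / r)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)

    cm = CountMatrix(pd.DataFrame(counts, index=genes_df.index, columns=sample_ids), samples)
    tmap = TripletMap(trips_df[["copy1", "copy2", "copy3"]].copy())
    truth = TruthLabels(triplets=trips_df.drop(columns=["copy1", "copy2", "copy3"]), genes=genes_df)
    return cm, tmap, lengths, truth


def make_term_map(
    truth: TruthLabels,
    enriched_term_size: int,
    background_terms: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene -> term table with one term planted to be enriched in Class-1 genes.

    The planted term ``TERM_ENR`` covers ``enriched_term_size`` genes drawn
    from members of planted Class-1 triplets; every gene is additionally
    assigned to one of ``background_terms`` uniform terms (if any).
    """
    rng = np.random.default_rng(seed)
    class1_anchors = truth.triplets.index[truth.triplets["class"] == "class1"]
    class1_genes = sorted(truth.genes.index[truth.genes["anchor"].isin(class1_anchors)])
    if enriched_term_size > len(class1_genes):
        raise HomeotripError(
            f"enriched_term_size={enriched_term_size} exceeds the {len(class1_genes)} planted Class-1 genes"
        )
    chosen = rng.choice(class1_genes, size=enriched_term_size, replace=False)
    rows = [{"gene": g, "term": "TERM_ENR"} for g in sorted(chosen)]
    if background_terms > 0:
        all_genes = sorted(truth.genes.index)
        assign = rng.integers(0, background_terms, len(all_genes))
        rows.extend({"gene": g, "term": f"TERM{j:04d}"} for g, j in zip(all_genes, assign))
    return pd.DataFrame(rows, columns=["gene", "term"])


def simulate_coexpression_blocks(
    n_blocks: int = 2,
    genes_per_block: int = 50,
    n_background: int = 50,
    n_samples: int = 12,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Log-scale expression with planted coexpressed blocks.

    Each block shares a latent profile across samples; member genes are the
    latent profile plus Gaussian noise, so within-block Pearson r is high
    and between-block r is low.  Background genes are pure noise.  Returns a
    gene x sample DataFrame on the TPM-like positive scale (2**x).
    """
    rng = np.random.default_rng(seed)
    profiles = rng.normal(0, 1, (n_blocks, n_samples))
    rows, ids = [], []
    for b in range(n_blocks):
        for g in range(genes_per_block):
            rows.append(5 + profiles[b] + rng.normal(0, noise_sd, n_samples))
            ids.append(f"BLOCK{b}.{g:03d}")
    for g in range(n_background):
        rows.append(5 + rng.normal(0, 1, n_samples))
        ids.append(f"BG.{g:03d}")
    x = np.asarray(rows)
    return pd.DataFrame(2.0**x, index=ids, columns=[f"s{j:02d}" for j in range(n_samples)])
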