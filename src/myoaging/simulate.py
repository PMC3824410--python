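"""Synthetic cohorts with planted age trends, concept weights, clinical and
qPCR tables.

The generator emulates a cross-sectional two-cohort muscle study: healthy
controls spanning young-to-old ages and mutation carriers spanning mid-life
ages.  Each gene belongs to one of four classes:

``null``
    no age trend in either cohort;
``concordant``
    the same nonzero slope in both cohorts (normal aging);
``accelerated``
    carrier slope = acceleration_factor x control slope (same sign, steeper);
``decelerated``
    carrier slope = control slope / acceleration_factor (same sign,
    shallower).

Expression is linear in age on the log2 scale with an additive sex offset and
homoscedastic Gaussian noise; ages are uniform over each cohort's range.
Every generator takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

GENE_CLASSES = ("null", "concordant", "accelerated", "decelerated")

#: Concepts used by default for the literature-association weight table.
DEFAULT_CONCEPTS = (
    "aging",
    "muscle contraction",
    "oxidative phosphorylation",
    "insulin signalling",
    "TGF-beta signalling",
    "ubiquitin-proteasome system",
)


@dataclass
class SimulationConfig:
    """Study conditions for the transcriptome simulator.

    Defaults mirror the cohorts the pipeline is designed around: 75 controls
    aged 17-89 and 22 carriers aged 31-74, with a strong aging effect
    (0.04 log2 units/year) doubled in accelerated genes.
    """

    n_genes: int = 1000
    n_control: int = 75
    n_carrier: int = 22
    control_age_range: tuple[float, float] = (17.0, 89.0)
    carrier_age_range: tuple[float, float] = (31.0, 74.0)
    fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "null": 0.7,
            "concordant": 0.1,
            "accelerated": 0.1,
            "decelerated": 0.1,
        }
    )
    base_slope: float = 0.04  # log2 units per year
    acceleration_factor: float = 2.0
    noise_sd: float = 0.3  # log2 units
    sex_effect: float = 0.1  # additive offset for females, log2 units
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.fractions.values()) - 1.0) > 1e-9:
            raise ValueError("gene-class fractions must sum to 1")
        if set(self.fractions) - set(GENE_CLASSES):
            raise ValueError(f"unknown gene classes: {set(self.fractions) - set(GENE_CLASSES)}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.acceleration_factor <= 0:
            raise ValueError("acceleration_factor must be > 0")
        if self.n_control < 3 or self.n_carrier < 3:
            raise ValueError("cohort sizes must be >= 3")


@dataclass
class GroundTruth:
    """Planted per-gene truth and, optionally, a planted enriched gene set."""

    genes: pd.DataFrame  # gene_id, class, control_slope, carrier_slope, baseline
    enriched_sets: dict[str, set[int]] = field(default_factory=dict)

    def gene_ids(self, gene_class: str) -> list[int]:
        sub = self.genes[self.genes["class"] == gene_class]
        return sub["gene_id"].tolist()


def _assign_classes(cfg: SimulationConfig) -> np.ndarray:
    """Deterministic class counts: floor(fraction*n) per non-null class,
    remainder to null, so fixture counts are exact."""
    counts = {
        c: int(np.floor(cfg.fractions.get(c, 0.0) * cfg.n_genes))
        for c in ("concordant", "accelerated", "decelerated")
    }
    n_null = cfg.n_genes - sum(counts.values())
    if n_null < 0:
        raise ValueError("non-null fractions exceed 1")
    labels = (
        ["concordant"] * counts["concordant"]
        + ["accelerated"] * counts["accelerated"]
        + ["decelerated"] * counts["decelerated"]
        + ["null"] * n_null
    )
    return np.asarray(labels)


def generate_transcriptome_cohorts(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate the (expression, metadata, annotation, truth) bundle.

    Expression of gene g in sample s:

        baseline_g + slope_{g,cohort(s)} * (age_s - age_min)
        + sex_effect * 1[female_s] + N(0, noise_sd^2)

    where ``age_min`` is the minimum over both cohort age ranges, so a
    concordant gene follows one shared trajectory across cohorts.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    classes = _assign_classes(cfg)
    gene_ids = np.arange(10001, 10001 + cfg.n_genes)
    probe_ids = np.array([f"P{i:06d}" for i in range(1, cfg.n_genes + 1)])

    baseline = rng.normal(8.0, 1.5, size=cfg.n_genes)
    signs = rng.choice([-1.0, 1.0], size=cfg.n_genes)
    control_slope = np.where(classes == "null", 0.0, signs * cfg.base_slope)
    carrier_slope = control_slope.copy()
    carrier_slope[classes == "accelerated"] *= cfg.acceleration_factor
    carrier_slope[classes == "decelerated"] /= cfg.acceleration_factor

    age_min = min(cfg.control_age_range[0], cfg.carrier_age_range[0])
    ages = np.concatenate(
        [
            rng.uniform(*cfg.control_age_range, size=cfg.n_control),
            rng.uniform(*cfg.carrier_age_range, size=cfg.n_carrier),
        ]
    )
    cohort = np.array(["control"] * cfg.n_control + ["carrier"] * cfg.n_carrier)
    sex = rng.choice(["male", "female"], size=cfg.n_control + cfg.n_carrier)
    sample_ids = np.array(
        [f"CTL{i:03d}" for i in range(1, cfg.n_control + 1)]
        + [f"CAR{i:03d}" for i in range(1, cfg.n_carrier + 1)]
    )
    # carriers are pre-symptomatic before mid-life, symptomatic after
    stage = np.where(
        cohort == "carrier", np.where(ages < 45.0, "presymptomatic", "symptomatic"), "none"
    )

    slopes = np.where(cohort == "control", control_slope[:, None], carrier_slope[:, None])
    female = (sex == "female").astype(float)
    values = (
        baseline[:, None]
        + slopes * (ages - age_min)[None, :]
        + cfg.sex_effect * female[None, :]
        + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, len(ages)))
    )

    expr = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids)
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age_years": ages,
            "sex": sex,
            "cohort": cohort,
            "stage": stage,
            "tissue": "vastus lateralis",
        }
    )
    annot = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "gene_id": gene_ids,
            "symbol": [f"G{g}" for g in gene_ids],
        }
    )
    truth = GroundTruth(
        genes=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "probe_id": probe_ids,
                "class": classes,
                "control_slope": control_slope,
                "carrier_slope": carrier_slope,
                "baseline": baseline,
            }
        )
    )
    return expr, meta, annot, truth


def generate_concept_weights(
    genes: Sequence[int],
    enriched_set: set[int] | Sequence[int],
    concepts: Sequence[str] = DEFAULT_CONCEPTS,
    enriched_concept: str = "aging",
    enriched_shape: tuple[float, float] = (5.0, 1.0),
    background_shape: tuple[float, float] = (1.0, 5.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Raw literature-association weights for every (gene, concept) pair.

    For ``enriched_concept`` the genes of ``enriched_set`` draw from a
    right-shifted Beta distribution and everything else from a left-shifted
    one; all other concepts are pure background.  Returns a tidy table with
    columns gene_id, concept, raw_weight.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene list")
    enriched_set = set(enriched_set)
    if not enriched_set <= set(genes):
        raise ValueError("enriched_set must be a subset of genes")
    rng = np.random.default_rng(seed)
    frames = []
    for concept in concepts:
        in_set = np.isin(genes, list(enriched_set)) if concept == enriched_concept else np.zeros(
            len(genes), dtype=bool
        )
        w = rng.beta(*background_shape, size=len(genes))
        if in_set.any():
            w[in_set] = rng.beta(*enriched_shape, size=int(in_set.sum()))
        frames.append(pd.DataFrame({"gene_id": genes, "concept": concept, "raw_weight": w}))
    return pd.concat(frames, ignore_index=True)


def generate_clinical_table(
    n: int,
    age_range: tuple[float, float] = (31.0, 74.0),
    true_beta_per_muscle: Mapping[str, float] | None = None,
    sex_effect: float = 0.0,
    noise_sd: float = 0.3,
    seed: int = 0,
    grid: float | None = 0.5,
) -> pd.DataFrame:
    """Clinical strength table: per-muscle MRC scores declining with age.

    MRC = 5 + beta*(age - age_min) + sex_effect*1[female] + noise, clipped to
    [0, 5] and rounded to the MRC grid (0..5 in ``grid`` steps; ``grid=None``
    keeps continuous scores).
    """
    if n < 5:
        raise ValueError("need n >= 5 subjects")
    if true_beta_per_muscle is None:
        true_beta_per_muscle = {"iliopsoas": -0.07}
    rng = np.random.default_rng(seed)
    ages = rng.uniform(*age_range, size=n)
    sex = rng.choice(["male", "female"], size=n)
    female = (sex == "female").astype(float)
    table = pd.DataFrame(
        {"subject_id": [f"S{i:03d}" for i in range(1, n + 1)], "age_years": ages, "sex": sex}
    )
    for muscle, beta in true_beta_per_muscle.items():
        score = 5.0 + beta * (ages - age_range[0]) + sex_effect * female
        score = score + rng.normal(0.0, noise_sd, size=n)
        score = np.clip(score, 0.0, 5.0)
        if beta > 0 and np.all(score >= 5.0):
            warnings.warn(
                f"muscle {muscle!r}: positive beta saturates every MRC score at the "
                "healthy ceiling; the design is degenerate",
                stacklevel=2,
            )
        if grid is not None:
            score = np.round(score / grid) * grid
        table[muscle] = score
    return table


def generate_qpcr_table(
    fold_changes: Mapping[str, float],
    reference_group: str,
    n_replicates: int = 6,
    ct_sd: float = 0.0,
    seed: int = 0,
    target_base_ct: float = 24.0,
    housekeeping_ct: float = 18.0,
) -> pd.DataFrame:
    """Ct table whose delta-Ct differences encode the true fold changes.

    A group's target Ct sits log2(fold change) cycles *below* the reference
    target Ct (one fewer cycle per doubling); the housekeeping gene is flat.
    With ct_sd=0 the delta-delta-Ct method recovers the planted fold changes
    exactly.
    """
    if reference_group not in fold_changes:
        raise ValueError(f"reference group {reference_group!r} missing from fold_changes")
    if abs(fold_changes[reference_group] - 1.0) > 1e-12:
        raise ValueError("reference group must have fold change 1")
    for g, fc in fold_changes.items():
        if fc <= 0:
            raise ValueError(f"fold change for group {g!r} must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for group, fc in fold_changes.items():
        for r in range(1, n_replicates + 1):
            rows.append(
                {
                    "sample_id": f"{group}_{r}",
                    "group": group,
                    "target_ct": target_base_ct - np.log2(fc) + rng.normal(0.0, ct_sd),
                    "housekeeping_ct": housekeeping_ct + rng.normal(0.0, ct_sd),
                }
            )
    return pd.DataFrame(rows)
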