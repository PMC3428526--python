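"""Synthetic shotgun-proteomics data with known ground truth.

The generator emulates the statistical structure a label-free tissue pipeline
has to cope with, on the log2 scale:

    log2 intensity = protein baseline + peptide ionization offset
                     + group effect (DE proteins, second group only)
                     + sample offset + noise

A cell is *observed* with a probability that increases logistically with its
realized intensity, which produces missing-not-at-random dropout of
low-abundance peptides.  Observed cells carry an integer spectral count
coupled to intensity (Poisson with an intensity-dependent rate, minimum 1).
Decoy (reversed-sequence) peptides and shared (non-unique) peptides are mixed
in so the filtering rules have work to do.  The companion protein table is
produced by the package's own LFQ rollup.

Defaults mirror the study conditions of a small two-group tissue cohort:
5 vs 4 experimental samples labelled ER+/ER−, 500 proteins with 1+Poisson(6)
peptides each, 10 % differential proteins at ±1 log2 unit, residual noise sd
0.4.  Optional replicate control samples (whole-tissue technical replicates
and microdissected biological replicates) support the QC battery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .rollup import rollup_protein_table
from .tables import PeptideQuantTable, ProteinQuantTable, StudyDesign

__all__ = ["SimulationConfig", "SyntheticTruth", "SyntheticDataset",
           "generate_dataset", "truth_eval"]


@dataclass(frozen=True)
class SimulationConfig:
    """All generator knobs; every random feature is driven by ``seed``."""

    n_proteins: int = 500
    peptides_per_protein_mean: float = 6.0   # count ~ 1 + Poisson(mean)
    n_samples_per_group: tuple[int, int] = (5, 4)
    group_labels: tuple[str, str] = ("ER+", "ER-")
    frac_de: float = 0.1
    log2_effect: float = 1.0                 # magnitude; sign random per protein
    baseline_mean: float = 25.0              # protein baseline N(mean, sd), log2
    baseline_sd: float = 2.0
    peptide_offset_sd: float = 1.5
    sample_offset_sd: float = 0.2
    noise_sd: float = 0.4
    detection_midpoint: float = 21.0         # logistic MNAR dropout; -inf = always seen
    detection_slope: float = 0.7
    count_rate: float = 2.0                  # spectral counts ~ max(1, Pois(rate * 2^((x-25)/4)))
    frac_shared_peptides: float = 0.05
    frac_reverse: float = 0.02
    n_wtl_ctrl: int = 0                      # technical replicate controls
    n_lcm_ctrl: int = 0                      # microdissected biological replicates
    wtl_noise_scale: float = 0.5
    lcm_noise_scale: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        if min(self.n_samples_per_group) <= 0:
            raise ValueError("both groups need at least one sample")
        for name in ("frac_de", "frac_shared_peptides", "frac_reverse"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("baseline_sd", "peptide_offset_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SyntheticTruth:
    """Ground truth for every generated feature."""

    proteins: pd.DataFrame        # is_de, log2_effect (group2 − group1), baseline
    expected_log2: pd.DataFrame   # per-protein expected log2 abundance per sample
    peptides: pd.DataFrame        # parent protein, ionization offset
    config: SimulationConfig

    @property
    def de_ids(self) -> list[str]:
        return list(self.proteins.index[self.proteins["is_de"]])


@dataclass
class SyntheticDataset:
    peptides: PeptideQuantTable
    proteins: ProteinQuantTable
    design: StudyDesign
    truth: SyntheticTruth


def _design_frame(cfg: SimulationConfig) -> StudyDesign:
    rows = []
    for i in range(cfg.n_wtl_ctrl):
        rows.append((f"WTL{i + 1:02d}", "WTL-CTRL", ""))
    for i in range(cfg.n_lcm_ctrl):
        rows.append((f"LCM{i + 1:02d}", "LCM-CTRL", ""))
    k = 0
    for label, count in zip(cfg.group_labels, cfg.n_samples_per_group):
        for _ in range(count):
            k += 1
            rows.append((f"S{k:02d}", "EXPERIMENTAL", label))
    frame = pd.DataFrame(
        {
            "sample_class": [r[1] for r in rows],
            "group_label": [r[2] for r in rows],
            "order_index": np.arange(len(rows)),
        },
        index=pd.Index([r[0] for r in rows], name="sample_id"),
    )
    return StudyDesign(frame)


def generate_dataset(config: SimulationConfig | None = None, **overrides) -> SyntheticDataset:
    """Draw one complete dataset (peptide + protein tables, design, truth)."""
    cfg = replace(config or SimulationConfig(), **overrides) if overrides else (
        config or SimulationConfig()
    )
    rng = np.random.default_rng(cfg.seed)
    design = _design_frame(cfg)
    samples = design.samples
    n_s = len(samples)
    classes = design.frame["sample_class"].reindex(samples).to_numpy()
    noise_scale = np.where(
        classes == "WTL-CTRL", cfg.wtl_noise_scale,
        np.where(classes == "LCM-CTRL", cfg.lcm_noise_scale, 1.0),
    )
    in_group2 = np.array(
        [design.frame.loc[s, "group_label"] == cfg.group_labels[1] for s in samples]
    )

    prot_ids = [f"P{i + 1:04d}" for i in range(cfg.n_proteins)]
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_proteins)
    n_de = int(round(cfg.frac_de * cfg.n_proteins))
    de_idx = rng.choice(cfg.n_proteins, size=n_de, replace=False)
    effect = np.zeros(cfg.n_proteins)
    if n_de:
        effect[de_idx] = cfg.log2_effect * rng.choice([-1.0, 1.0], size=n_de)

    n_pep = 1 + rng.poisson(cfg.peptides_per_protein_mean, cfg.n_proteins)
    parent = np.repeat(np.arange(cfg.n_proteins), n_pep)
    n_peptides = len(parent)
    pep_offset = rng.normal(0.0, cfg.peptide_offset_sd, n_peptides)
    sample_offset = rng.normal(0.0, cfg.sample_offset_sd, n_s)

    # decoy peptides: their own decoy "protein groups", same intensity model
    n_rev = int(round(cfg.frac_reverse * n_peptides))
    rev_baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, n_rev)
    rev_offset = rng.normal(0.0, cfg.peptide_offset_sd, n_rev)

    expected_fwd = (
        baseline[parent][:, None]
        + pep_offset[:, None]
        + np.where(in_group2[None, :], effect[parent][:, None], 0.0)
        + sample_offset[None, :]
    )
    expected_rev = rev_baseline[:, None] + rev_offset[:, None] + sample_offset[None, :]
    expected = np.vstack([expected_fwd, expected_rev]) if n_rev else expected_fwd
    total = expected.shape[0]

    realized = expected + rng.normal(0.0, cfg.noise_sd, size=expected.shape) * noise_scale
    if math.isinf(cfg.detection_midpoint) and cfg.detection_midpoint < 0:
        observed = np.ones_like(realized, dtype=bool)
    else:
        p_detect = expit(cfg.detection_slope * (realized - cfg.detection_midpoint))
        observed = rng.random(size=realized.shape) < p_detect

    lam = cfg.count_rate * np.power(2.0, (realized - cfg.baseline_mean) / 4.0)
    counts = np.maximum(1, rng.poisson(np.minimum(lam, 1e6)))
    counts = np.where(observed, counts, 0)
    intensity = np.where(observed, np.power(2.0, realized), np.nan)

    pep_keys = [f"PEP{i + 1:05d}" for i in range(total)]
    groups: list[tuple[str, ...]] = [(prot_ids[p],) for p in parent]
    groups += [(f"REV__P{i + 1:04d}",) for i in range(n_rev)]
    is_rev = np.array([False] * n_peptides + [True] * n_rev)

    # a fraction of forward peptides additionally maps to a second protein
    n_shared = int(round(cfg.frac_shared_peptides * n_peptides))
    if n_shared and cfg.n_proteins > 1:
        shared_idx = rng.choice(n_peptides, size=n_shared, replace=False)
        for i in shared_idx:
            other = int(rng.integers(cfg.n_proteins - 1))
            if other >= parent[i]:
                other += 1
            groups[i] = (prot_ids[parent[i]], prot_ids[other])

    idx = pd.Index(pep_keys, name="peptide_key")
    peptides = PeptideQuantTable(
        intensity=pd.DataFrame(intensity, index=idx, columns=samples),
        msms=pd.DataFrame(counts, index=idx, columns=samples),
        protein_groups=pd.Series(groups, index=idx, name="protein_groups"),
        is_reverse=pd.Series(is_rev, index=idx, name="is_reverse"),
    )
    proteins = rollup_protein_table(peptides, min_shared=1)

    truth_prot = pd.DataFrame(
        {
            "is_de": effect != 0.0,
            "log2_effect": effect,
            "baseline": baseline,
            "n_peptides": n_pep,
        },
        index=pd.Index(prot_ids, name="protein_group_id"),
    )
    expected_prot = (
        baseline[:, None]
        + np.where(in_group2[None, :], effect[:, None], 0.0)
        + sample_offset[None, :]
    )
    truth = SyntheticTruth(
        proteins=truth_prot,
        expected_log2=pd.DataFrame(
            expected_prot, index=truth_prot.index, columns=samples
        ),
        peptides=pd.DataFrame(
            {
                "parent": [prot_ids[p] for p in parent]
                + [f"REV__P{i + 1:04d}" for i in range(n_rev)],
                "offset": np.concatenate([pep_offset, rev_offset])
                if n_rev
                else pep_offset,
            },
            index=idx,
        ),
        config=cfg,
    )
    return SyntheticDataset(peptides=peptides, proteins=proteins, design=design, truth=truth)


def truth_eval(selected_ids, truth: SyntheticTruth, universe=None) -> dict[str, float]:
    """Confusion counts, empirical FDR and power of a selected protein set.

    ``universe`` restricts the evaluation (e.g. to proteins that survived the
    rollup); by default every simulated forward protein counts.
    """
    if universe is None:
        universe = list(truth.proteins.index)
    universe = [u for u in universe if u in truth.proteins.index]
    selected = set(selected_ids) & set(universe)
    de = set(truth.de_ids) & set(universe)
    tp = len(selected & de)
    fp = len(selected - de)
    fn = len(de - selected)
    tn = len(universe) - tp - fp - fn
    return {
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "fdr": fp / (tp + fp) if (tp + fp) else 0.0,
        "power": tp / (tp + fn) if (tp + fn) else float("nan"),
    }
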