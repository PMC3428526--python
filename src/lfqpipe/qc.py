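"""Replicate quality control for shotgun-proteomics quantification tables.

Implements the QC battery used to judge a label-free tissue workflow:

* per-sample identification counts (a feature is "identified in a sample"
  when its intensity is observed there) and per-class mean ± sd with the
  coefficient of variation (CV%);
* pairwise Pearson correlations of log2 abundances over pairwise-complete
  positions, summarised per sample class;
* reproducibility tiers: a feature seen in ≤ 1/3 of a class's samples is
  low-reproducibility, ≥ 2/3 high, in between medium — reproducing the
  printed "≤33 %, 34–66 %, ≥67 %" bands for class sizes such as 12, 5 and 9;
* per-feature CV% of the *linear-scale* intensities for features observed in
  at least two samples of a class;
* overlap (shared / exclusive counts and percentages) between the protein
  sets identified in two sample classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import PeptideQuantTable, ProteinQuantTable, StudyDesign

__all__ = [
    "identification_counts",
    "count_summary",
    "pairwise_pearson",
    "reproducibility_tiers",
    "feature_cv",
    "set_overlap",
    "QCReport",
    "build_qc_report",
]


def _quant_frame(table) -> pd.DataFrame:
    return table.intensity if isinstance(table, PeptideQuantTable) else table.abundance


def identification_counts(table) -> pd.DataFrame:
    """Features observed (non-missing intensity) per sample.

    Peptide tables additionally report the unique-peptide-only count.
    """
    quant = _quant_frame(table)
    out = pd.DataFrame({"total": quant.notna().sum(axis=0)})
    if isinstance(table, PeptideQuantTable):
        out["unique"] = quant[table.is_unique].notna().sum(axis=0)
    out.index.name = "sample_id"
    return out


def count_summary(
    per_sample_counts: pd.Series, design: StudyDesign, sample_class: str
) -> dict[str, float]:
    """Mean, sample sd (n−1) and CV% of identification counts in a class."""
    samples = design.class_samples(sample_class)
    vals = per_sample_counts.reindex(samples).dropna().to_numpy(dtype=float)
    mean = float(vals.mean()) if len(vals) else float("nan")
    if len(vals) >= 2:
        sd = float(vals.std(ddof=1))
        cv = 100.0 * sd / mean if mean != 0 else float("nan")
    else:
        sd = cv = float("nan")
    return {"n": len(vals), "mean": mean, "sd": sd, "cv_pct": cv}


def pairwise_pearson(
    log2_matrix: pd.DataFrame,
    design: StudyDesign,
    sample_class: str,
    min_shared: int = 3,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Pearson r between all sample pairs of a class (pairwise-complete).

    Pairs sharing fewer than ``min_shared`` observed positions get a missing
    correlation and are excluded from the mean ± sd summary.
    """
    samples = [s for s in design.class_samples(sample_class)
               if s in log2_matrix.columns]
    if len(samples) < 2:
        raise ValueError(f"class {sample_class!r} has fewer than 2 samples")
    vals = log2_matrix[samples].to_numpy(dtype=float)
    n = len(samples)
    corr = np.full((n, n), np.nan)
    np.fill_diagonal(corr, 1.0)
    offdiag = []
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~np.isnan(vals[:, i]) & ~np.isnan(vals[:, j])
            if shared.sum() < min_shared:
                continue
            x, y = vals[shared, i], vals[shared, j]
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            corr[i, j] = corr[j, i] = r
            offdiag.append(r)
    summary = {
        "n_pairs": len(offdiag),
        "mean": float(np.mean(offdiag)) if offdiag else float("nan"),
        "sd": float(np.std(offdiag, ddof=1)) if len(offdiag) >= 2 else float("nan"),
    }
    return pd.DataFrame(corr, index=samples, columns=samples), summary


def reproducibility_tiers(
    table, design: StudyDesign, sample_class: str
) -> dict[str, float]:
    """Fractions of class features in the low/medium/high observation tiers."""
    samples = design.class_samples(sample_class)
    if len(samples) < 2:
        raise ValueError(f"class {sample_class!r} has fewer than 2 samples")
    quant = _quant_frame(table)[samples]
    n_obs = quant.notna().sum(axis=1)
    n_obs = n_obs[n_obs >= 1]
    frac = n_obs / len(samples)
    low = float((frac <= 1 / 3).mean())
    high = float((frac >= 2 / 3).mean())
    return {
        "n_features": int(len(frac)),
        "low": low,
        "medium": 1.0 - low - high,
        "high": high,
    }


def feature_cv(
    table, design: StudyDesign, sample_class: str
) -> tuple[pd.Series, dict[str, float]]:
    """Per-feature CV% of linear intensities within a class (≥2 observations)."""
    samples = design.class_samples(sample_class)
    quant = _quant_frame(table)[samples]
    n_obs = quant.notna().sum(axis=1)
    sub = quant[n_obs >= 2]
    mean = sub.mean(axis=1, skipna=True)
    sd = sub.std(axis=1, ddof=1, skipna=True)
    cv = (100.0 * sd / mean).rename("cv_pct")
    summary = {
        "n_features": int(len(cv)),
        "mean": float(cv.mean()) if len(cv) else float("nan"),
        "sd": float(cv.std(ddof=1)) if len(cv) >= 2 else float("nan"),
    }
    return cv, summary


def set_overlap(set_a, set_b) -> dict[str, float]:
    """Shared / exclusive counts and percentages of the union."""
    a, b = set(set_a), set(set_b)
    union = a | b
    shared = a & b
    n_union = len(union)

    def pct(k: int) -> float:
        return 100.0 * k / n_union if n_union else float("nan")

    return {
        "union": n_union,
        "shared": len(shared),
        "only_a": len(a - b),
        "only_b": len(b - a),
        "shared_pct": pct(len(shared)),
        "only_a_pct": pct(len(a - b)),
        "only_b_pct": pct(len(b - a)),
    }


@dataclass
class QCReport:
    """All QC metric families, one tidy frame per family."""

    identification: pd.DataFrame      # per sample and level
    count_summaries: pd.DataFrame     # per class and level
    pearson_summaries: pd.DataFrame   # per class and level
    tier_fractions: pd.DataFrame      # per class and level
    cv_summaries: pd.DataFrame        # per class and level
    overlaps: pd.DataFrame            # per class pair (protein level)

    def write(self, path) -> None:
        """Multi-section TSV, deterministic."""
        with open(path, "w") as fh:
            for name in (
                "identification",
                "count_summaries",
                "pearson_summaries",
                "tier_fractions",
                "cv_summaries",
                "overlaps",
            ):
                frame = getattr(self, name)
                fh.write(f"# section: {name}\n")
                fh.write(frame.to_csv(sep="\t", na_rep="NA", float_format="%.6g"))


def build_qc_report(
    peptides: PeptideQuantTable,
    proteins: ProteinQuantTable,
    design: StudyDesign,
) -> QCReport:
    """Compute the full QC battery over every sample class with ≥2 samples."""
    classes = [
        cls
        for cls in ("WTL-CTRL", "LCM-CTRL", "EXPERIMENTAL")
        if len(design.class_samples(cls)) >= 2
    ]
    levels = {"peptide": peptides, "protein": proteins}

    ident_rows = []
    for level, table in levels.items():
        counts = identification_counts(table)
        for sid, row in counts.iterrows():
            rec = {"level": level, "sample_id": sid, "total": int(row["total"])}
            if "unique" in counts.columns:
                rec["unique"] = int(row["unique"])
            ident_rows.append(rec)
    identification = pd.DataFrame(ident_rows).set_index(["level", "sample_id"])

    cs_rows, pr_rows, tier_rows, cv_rows = [], [], [], []
    for level, table in levels.items():
        counts = identification_counts(table)["total"]
        quant = _quant_frame(table)
        log2 = np.log2(quant)
        for cls in classes:
            cs_rows.append(
                {"level": level, "sample_class": cls, **count_summary(counts, design, cls)}
            )
            _, psum = pairwise_pearson(log2, design, cls)
            pr_rows.append({"level": level, "sample_class": cls, **psum})
            tier_rows.append(
                {"level": level, "sample_class": cls,
                 **reproducibility_tiers(table, design, cls)}
            )
            _, csum = feature_cv(table, design, cls)
            cv_rows.append({"level": level, "sample_class": cls, **csum})

    prot_abund = proteins.abundance
    overlap_rows = []
    for i, cls_a in enumerate(classes):
        for cls_b in classes[i + 1:]:
            ids_a = prot_abund.index[
                prot_abund[design.class_samples(cls_a)].notna().any(axis=1)
            ]
            ids_b = prot_abund.index[
                prot_abund[design.class_samples(cls_b)].notna().any(axis=1)
            ]
            overlap_rows.append(
                {"class_a": cls_a, "class_b": cls_b, **set_overlap(ids_a, ids_b)}
            )
    overlaps = (
        pd.DataFrame(overlap_rows).set_index(["class_a", "class_b"])
        if overlap_rows
        else pd.DataFrame(
            columns=["class_a", "class_b", "union", "shared", "only_a", "only_b",
                     "shared_pct", "only_a_pct", "only_b_pct"]
        ).set_index(["class_a", "class_b"])
    )
    return QCReport(
        identification=identification,
        count_summaries=pd.DataFrame(cs_rows).set_index(["level", "sample_class"]),
        pearson_summaries=pd.DataFrame(pr_rows).set_index(["level", "sample_class"]),
        tier_fractions=pd.DataFrame(tier_rows).set_index(["level", "sample_class"]),
        cv_summaries=pd.DataFrame(cv_rows).set_index(["level", "sample_class"]),
        overlaps=overlaps,
    )
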