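"""Descriptive summaries of a core-clade run.

Prevalence-vs-divergence correlation (recently diverged clades tend to be
rarer), top-quartile clade selection, clustering of per-study prevalence
profiles, and a machine-readable run report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

__all__ = [
    "prevalence_divergence_correlation",
    "top_quartile_clades",
    "cluster_prevalence_profiles",
    "RunReport",
]


def prevalence_divergence_correlation(
    divergence: Sequence[float], prevalence: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation between within-clade tip-to-tip divergence
    and observed clade prevalence, with its two-sided p-value."""
    d = np.asarray(divergence, dtype=float)
    p = np.asarray(prevalence, dtype=float)
    if len(d) != len(p):
        raise ValueError("inputs have different lengths")
    if len(d) < 3:
        raise ValueError("need at least 3 clades")
    rho, pval = stats.spearmanr(d, p)
    return float(rho), float(pval)


def top_quartile_clades(prevalence: dict[str, float]) -> set[str]:
    """Clades at or above the 75th percentile of prevalence.

    Uses linear-interpolation percentiles; ties at the threshold are
    included, so with all-equal prevalences every clade is returned.
    """
    if len(prevalence) < 4:
        raise ValueError("need at least 4 clades for a quartile split")
    vals = np.array(list(prevalence.values()), dtype=float)
    thresh = np.percentile(vals, 75, method="linear")
    return {c for c, v in prevalence.items() if v >= thresh}


def cluster_prevalence_profiles(
    matrix: pd.DataFrame, k: int = 3, seed: int = 0
) -> pd.DataFrame:
    """Cluster clades by their per-study prevalence profile.

    Average-linkage hierarchical clustering on Euclidean distance, cut at
    ``k`` clusters, plus k-means with the same ``k`` (fixed seed); both
    labelings are returned, one row per clade.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(matrix):
        raise ValueError("k exceeds the number of clades")
    X = matrix.to_numpy(dtype=float)
    if k == 1:
        hier = np.ones(len(matrix), dtype=int)
        km = np.zeros(len(matrix), dtype=int)
    else:
        Z = linkage(X, method="average", metric="euclidean")
        hier = fcluster(Z, t=k, criterion="maxclust")
        km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(X)
    return pd.DataFrame(
        {"hierarchical": hier, "kmeans": km}, index=matrix.index
    )


@dataclass
class RunReport:
    """Accumulates per-stage dimensions, seeds and summary statistics."""

    config: dict[str, Any] = field(default_factory=dict)
    seeds: dict[str, int] = field(default_factory=dict)
    stages: list[dict[str, Any]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    summary: dict[str, Any] = field(default_factory=dict)

    def add_stage(self, name: str, **dims: Any) -> None:
        self.stages.append({"stage": name, **dims})

    def to_dict(self) -> dict[str, Any]:
        return {
            "config": self.config,
            "seeds": self.seeds,
            "stages": self.stages,
            "warnings": self.warnings,
            "summary": self.summary,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    def write_markdown(self, path: str | Path) -> None:
        lines = ["# Run report", "", "## Configuration"]
        for key, val in sorted(self.config.items()):
            lines.append(f"- {key}: {val}")
        lines += ["", "## Seeds"]
        for key, val in sorted(self.seeds.items()):
            lines.append(f"- {key}: {val}")
        lines += ["", "## Stages"]
        for st in self.stages:
            dims = ", ".join(f"{k}={v}" for k, v in st.items() if k != "stage")
            lines.append(f"- {st['stage']}: {dims}")
        lines += ["", "## Summary"]
        for key, val in sorted(self.summary.items()):
            lines.append(f"- {key}: {val}")
        if self.warnings:
            lines += ["", "## Warnings"]
            lines += [f"- {w}" for w in self.warnings]
        Path(path).write_text("\n".join(lines) + "\n")
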