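"""Ecophylogenetic core-clade detection.

The test asks, for every monophyletic clade in the ASV phylogeny, whether
the clade is present (nonzero agglomerated abundance) in more samples than
expected when tip labels are assigned to the tree at random.  Steps:

1. *Agglomerate*: each clade's abundance in a sample is the sum of its
   member tips' counts — the "clade diversity matrix".
2. *Observe*: clade prevalence = fraction of selected samples with nonzero
   clade abundance.
3. *Null*: repeatedly permute the tip<->ASV-label association (one joint
   permutation per replicate, shared by all clades), recompute every
   clade's prevalence, and accumulate the null mean and SD.
4. *Test*: z = (observed - null mean) / null SD, one-sided upper-tail
   normal p, Benjamini–Hochberg FDR across clades; clades with q below the
   threshold are called core.

The permutation keeps topology and the count table fixed, so the null
distribution of a clade's prevalence depends only on its tip count — a
property the tests exploit as an internal consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .asv_table import AsvCountTable, SampleFilter, _select_samples
from .phylo import Phylogeny, enumerate_clades

__all__ = [
    "CladeAbundanceMatrix",
    "NullMoments",
    "CoreCladeResult",
    "clade_abundance",
    "clade_prevalence",
    "permutation_null",
    "call_core",
    "find_core_clades",
]

DEFAULT_N_PERM = 999
DEFAULT_ALPHA = 0.05


@dataclass
class CladeAbundanceMatrix:
    """Clades x samples integer matrix of agglomerated member-tip counts."""

    abundance: pd.DataFrame  # index: clade ids, columns: sample ids

    @property
    def clade_ids(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundance.columns)

    def write_tsv(self, path) -> None:
        out = self.abundance.copy()
        out.index.name = "clade_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "CladeAbundanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(abundance=df.astype(np.int64))


@dataclass
class NullMoments:
    null_mean: float
    null_sd: float
    exceedances: int | None = None  # permutations with prevalence >= observed
    n_perm: int | None = None


@dataclass
class CoreCladeResult:
    clade_id: str
    n_tips: int
    observed_prevalence: float
    null_mean: float
    null_sd: float
    z: float
    p: float
    q: float
    is_core: bool
    p_exact: float | None = None  # permutation-rank p, diagnostic
    per_study_prevalence: dict[str, float] | None = None
    msp: float | None = None


# -- tree <-> array plumbing ----------------------------------------------


def _tree_arrays(tree: Phylogeny, min_tips: int = 2):
    """Postorder node indexing for vectorised clade computations.

    Returns tip labels (postorder), per-internal-node child index lists,
    internal clade ids and tip counts, plus the indices of internal nodes
    meeting ``min_tips``.
    """
    tip_labels: list[str] = []
    node_index: dict[int, int] = {}
    children: list[list[int]] = []
    clade_ids: list[str] = []
    ntips_arr: list[int] = []
    idx = 0
    internal_rows: list[int] = []
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            node_index[id(node)] = idx
            tip_labels.append(node.taxon.label)
            idx += 1
    n_leaves = idx
    tipcount: dict[int, int] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            tipcount[id(node)] = 1
            continue
        node_index[id(node)] = idx
        kids = [node_index[id(c)] for c in node.child_nodes()]
        children.append(kids)
        tc = sum(tipcount[id(c)] for c in node.child_nodes())
        tipcount[id(node)] = tc
        clade_ids.append(node.clade_id)
        ntips_arr.append(tc)
        if tc >= min_tips:
            internal_rows.append(idx - n_leaves)
        idx += 1
    return tip_labels, children, clade_ids, np.asarray(ntips_arr), internal_rows


# -- clade abundance -------------------------------------------------------


def clade_abundance(
    tree: Phylogeny, table: AsvCountTable, min_tips: int = 2
) -> CladeAbundanceMatrix:
    """Sum member-tip counts per clade and sample (postorder accumulation)."""
    tip_labels, children, clade_ids, ntips, rows = _tree_arrays(tree, min_tips)
    missing = set(tip_labels) - set(table.asv_ids)
    if missing:
        raise KeyError(
            f"{len(missing)} tree tip(s) missing from count table: "
            + ", ".join(sorted(missing)[:5])
        )
    counts = table.counts[tip_labels].to_numpy().T  # tips x samples
    n_leaves = len(tip_labels)
    n_nodes = n_leaves + len(children)
    acc = np.zeros((n_nodes, counts.shape[1]), dtype=np.int64)
    acc[:n_leaves] = counts
    for k, kids in enumerate(children):
        acc[n_leaves + k] = acc[kids].sum(axis=0)
    internal = acc[n_leaves:]
    df = pd.DataFrame(
        internal[rows],
        index=[clade_ids[r] for r in rows],
        columns=table.counts.index,
    )
    return CladeAbundanceMatrix(abundance=df)


def clade_prevalence(
    matrix: CladeAbundanceMatrix,
    metadata: pd.DataFrame | None = None,
    sample_filter: SampleFilter | None = None,
) -> dict[str, float]:
    """Fraction of selected samples where each clade has nonzero abundance."""
    if metadata is not None or sample_filter is not None:
        meta = metadata if metadata is not None else pd.DataFrame(
            index=matrix.abundance.columns
        )
        selected = _select_samples(pd.Index(matrix.sample_ids), meta, sample_filter)
    else:
        selected = matrix.sample_ids
    if not selected:
        raise ValueError("sample filter selects no samples")
    sub = matrix.abundance[selected]
    prev = (sub > 0).mean(axis=1)
    return {cid: float(v) for cid, v in prev.items()}


# -- permutation null ------------------------------------------------------


def permutation_null(
    tree: Phylogeny,
    table: AsvCountTable,
    sample_filter: Sequence = None,
    metadata: pd.DataFrame | None = None,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    min_tips: int = 2,
    observed: dict[str, float] | None = None,
) -> dict[str, NullMoments]:
    """Null prevalence moments from joint tip-label permutations.

    Each replicate draws one uniform permutation of the tip<->ASV-label
    assignment over *all* tips, recomputes every clade's prevalence from
    the permuted presence matrix, and accumulates per-clade mean and
    (sample) SD over ``n_perm`` replicates.  Passing the observed
    prevalences additionally records exceedance counts for an exact
    permutation-rank p-value.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    tip_labels, children, clade_ids, ntips, rows = _tree_arrays(tree, min_tips)
    if metadata is not None or (
        sample_filter is not None and not isinstance(sample_filter, (list, tuple, set))
    ):
        meta = metadata if metadata is not None else pd.DataFrame(
            index=table.counts.index
        )
        selected = _select_samples(table.counts.index, meta, sample_filter)
    elif sample_filter is not None:
        wanted = set(sample_filter)
        selected = [s for s in table.sample_ids if s in wanted]
    else:
        selected = table.sample_ids
    if not selected:
        raise ValueError("sample filter selects no samples")

    presence = (table.counts.loc[selected, tip_labels].to_numpy() > 0).T  # tips x S
    n_tips, n_samp = presence.shape
    n_internal = len(children)
    rng = np.random.default_rng(seed)

    kid_arrays = [np.asarray(k) for k in children]
    acc = np.empty((n_tips + n_internal, n_samp), dtype=bool)
    s1 = np.zeros(n_internal)
    s2 = np.zeros(n_internal)
    obs_vec = None
    exceed = None
    if observed is not None:
        obs_vec = np.array([observed[clade_ids[r]] for r in rows])
        exceed = np.zeros(len(rows), dtype=np.int64)

    prev = np.empty(n_internal)
    for _ in range(n_perm):
        perm = rng.permutation(n_tips)
        acc[:n_tips] = presence[perm]
        for k, kids in enumerate(kid_arrays):
            if len(kids) == 2:
                np.logical_or(acc[kids[0]], acc[kids[1]], out=acc[n_tips + k])
            else:
                acc[n_tips + k] = np.logical_or.reduce(acc[kids])
        np.mean(acc[n_tips:], axis=1, out=prev)
        s1 += prev
        s2 += prev * prev
        if obs_vec is not None:
            exceed += prev[rows] >= obs_vec - 1e-12

    mean = s1 / n_perm
    var = (s2 - n_perm * mean * mean) / max(n_perm - 1, 1)
    sd = np.sqrt(np.clip(var, 0.0, None))
    out: dict[str, NullMoments] = {}
    for j, r in enumerate(rows):
        out[clade_ids[r]] = NullMoments(
            null_mean=float(mean[r]),
            null_sd=float(sd[r]),
            exceedances=None if exceed is None else int(exceed[j]),
            n_perm=n_perm,
        )
    return out


# -- core calling ----------------------------------------------------------


def call_core(
    observed: dict[str, float],
    null_moments: dict[str, NullMoments],
    alpha: float = DEFAULT_ALPHA,
    fdr_method: str = "fdr_bh",
    n_tips: dict[str, int] | None = None,
) -> list[CoreCladeResult]:
    """z-test each clade's prevalence against its permutation null, with FDR.

    p is the one-sided upper-tail normal probability (core means *more*
    prevalent than chance).  Degenerate nulls (SD = 0) get the conservative
    permutation-floor convention: p = 1/(n_perm+1) when the observation
    exceeds the null mean, else p = 1.
    """
    if set(observed) != set(null_moments):
        raise ValueError("observed and null_moments must share clade ids")
    clade_ids = sorted(observed, key=_clade_sort_key)
    zs, ps = [], []
    for cid in clade_ids:
        nm = null_moments[cid]
        obs = observed[cid]
        if nm.null_sd > 0:
            z = (obs - nm.null_mean) / nm.null_sd
            p = float(stats.norm.sf(z))
        else:
            z = np.inf if obs > nm.null_mean else (0.0 if obs == nm.null_mean else -np.inf)
            if obs > nm.null_mean:
                p = 1.0 / ((nm.n_perm or DEFAULT_N_PERM) + 1)
            else:
                p = 1.0
        zs.append(z)
        ps.append(p)
    reject, qs, _, _ = multipletests(ps, alpha=alpha, method=fdr_method)[:4]
    results = []
    for cid, z, p, q, rej in zip(clade_ids, zs, ps, qs, reject):
        nm = null_moments[cid]
        p_exact = None
        if nm.exceedances is not None and nm.n_perm:
            p_exact = (1 + nm.exceedances) / (nm.n_perm + 1)
        results.append(
            CoreCladeResult(
                clade_id=cid,
                n_tips=0 if n_tips is None else n_tips.get(cid, 0),
                observed_prevalence=observed[cid],
                null_mean=nm.null_mean,
                null_sd=nm.null_sd,
                z=float(z),
                p=float(p),
                q=float(q),
                is_core=bool(q < alpha) and observed[cid] > nm.null_mean,
                p_exact=p_exact,
            )
        )
    return results


def _clade_sort_key(cid: str):
    tail = cid[4:] if cid.startswith("node") else cid
    return (0, int(tail)) if tail.isdigit() else (1, cid)


# -- one-call pipeline stage -----------------------------------------------


def find_core_clades(
    tree: Phylogeny,
    table: AsvCountTable,
    metadata: pd.DataFrame,
    sample_filter: SampleFilter | None = None,
    n_perm: int = DEFAULT_N_PERM,
    alpha: float = DEFAULT_ALPHA,
    seed: int | None = None,
    min_tips: int = 2,
    fdr_method: str = "fdr_bh",
) -> tuple[list[CoreCladeResult], CladeAbundanceMatrix]:
    """Full core-clade stage: agglomerate, observe, permute, test.

    Per-study prevalence and its median (MSP) are attached to each result
    alongside the pooled prevalence used for the test itself.
    """
    matrix = clade_abundance(tree, table, min_tips=min_tips)
    selected = _select_samples(table.counts.index, metadata, sample_filter)
    if not selected:
        raise ValueError("sample filter selects no samples")
    observed = clade_prevalence(matrix, sample_filter=selected)
    null = permutation_null(
        tree,
        table,
        sample_filter=selected,
        n_perm=n_perm,
        seed=seed,
        min_tips=min_tips,
        observed=observed,
    )
    ntips_map = {c.clade_id: c.n_tips for c in enumerate_clades(tree, min_tips=min_tips)}
    results = call_core(
        observed, null, alpha=alpha, fdr_method=fdr_method, n_tips=ntips_map
    )
    # per-study prevalence on the selected (control) samples
    studies = metadata.loc[selected, "study"]
    present = (matrix.abundance[selected] > 0).T  # samples x clades
    per_study = present.groupby(studies).mean()  # studies x clades
    for res in results:
        col = per_study[res.clade_id]
        res.per_study_prevalence = {s: float(v) for s, v in col.items()}
        res.msp = float(col.median())
    return results, matrix


def results_to_frame(results: list[CoreCladeResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "clade_id": r.clade_id,
            "n_tips": r.n_tips,
            "observed_prevalence": r.observed_prevalence,
            "null_mean": r.null_mean,
            "null_sd": r.null_sd,
            "z": r.z,
            "p": r.p,
            "q": r.q,
            "p_exact": r.p_exact,
            "is_core": r.is_core,
            "msp": r.msp,
        }
        if r.per_study_prevalence:
            for s, v in r.per_study_prevalence.items():
                row[f"prev_{s}"] = v
        rows.append(row)
    return pd.DataFrame(rows).set_index("clade_id")
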