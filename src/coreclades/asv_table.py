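"""ASV-level count-table operations.

Covers the table plumbing that precedes the clade analysis: merging ASVs
whose sequences are identical to or perfect substrings of other ASVs (so the
same organism sequenced in different studies collapses to one column),
rarefying every sample to a fixed read depth, and per-ASV prevalence
statistics including the median per-study prevalence (MSP).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AsvCountTable",
    "MergeMap",
    "AsvPrevalence",
    "merge_asvs",
    "rarefy",
    "asv_prevalence",
    "read_fasta",
    "write_fasta",
]

_DNA = set("ACGT")


@dataclass
class AsvCountTable:
    """A samples x ASVs matrix of non-negative integer counts.

    ``counts`` is indexed by sample id with one column per ASV id.
    ``sequences`` optionally maps ASV ids to uppercase DNA strings.
    """

    counts: pd.DataFrame
    sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        if c.columns.duplicated().any():
            raise ValueError("duplicate ASV ids")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integral")
            self.counts = c.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    # -- I/O -----------------------------------------------------------

    @classmethod
    def read_tsv(
        cls, path: str | Path, fasta: str | Path | None = None
    ) -> "AsvCountTable":
        counts = pd.read_csv(path, sep="\t", index_col=0)
        counts.index = counts.index.astype(str)
        seqs = read_fasta(fasta) if fasta is not None else None
        return cls(counts=counts, sequences=seqs)

    def write_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


@dataclass
class MergeMap:
    """Partition of ASV ids into merge groups keyed by their representative."""

    groups: dict[str, frozenset[str]] = field(default_factory=dict)

    def member_to_rep(self) -> dict[str, str]:
        return {m: rep for rep, grp in self.groups.items() for m in grp}

    def nontrivial(self) -> dict[str, frozenset[str]]:
        return {r: g for r, g in self.groups.items() if len(g) > 1}


@dataclass
class AsvPrevalence:
    """Prevalence summary for one ASV over a set of selected samples."""

    overall_prevalence: float
    msp: float  # median over studies of within-study prevalence
    study_occurrence: int  # number of studies with >=1 positive sample


# -- FASTA helpers ---------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# -- merging ---------------------------------------------------------------


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def merge_asvs(
    table: AsvCountTable,
    strict_alphabet: bool = True,
    match_revcomp: bool = False,
) -> tuple[AsvCountTable, MergeMap]:
    """Agglomerate ASVs whose sequence equals or is a substring of another's.

    Each ASV is assigned to a *maximal* representative — one whose sequence
    is not a proper substring of any other retained sequence — and group
    counts are summed per sample.  Ties are resolved deterministically:
    among identical sequences the lexicographically smallest ASV id is the
    representative, and a sequence contained in several non-nested
    representatives joins the longest one (then lexicographic on id).

    Matching is exact, case-insensitive and forward-strand by default; all
    source studies target the same amplicon, so reverse-complement hits are
    not expected (enable ``match_revcomp`` to also fold those in).
    """
    if table.sequences is None:
        raise ValueError("merge_asvs requires sequences for all ASVs")
    seqs: dict[str, str] = {}
    for asv in table.asv_ids:
        if asv not in table.sequences:
            raise ValueError(f"missing sequence for ASV {asv!r}")
        s = table.sequences[asv].upper()
        if strict_alphabet and (set(s) - _DNA):
            raise ValueError(
                f"ASV {asv!r} contains bases outside ACGT; "
                "pass strict_alphabet=False to accept"
            )
        seqs[asv] = s

    def contains(hay: str, needle: str) -> bool:
        if needle in hay:
            return True
        return match_revcomp and _revcomp(needle) in hay

    # canonical id per distinct sequence: lexicographically smallest
    seq_to_ids: dict[str, list[str]] = {}
    for asv in sorted(seqs):
        seq_to_ids.setdefault(seqs[asv], []).append(asv)
    uniq = sorted(seq_to_ids, key=lambda s: (-len(s), seq_to_ids[s][0]))

    # maximal sequences: not a proper substring of any other distinct sequence
    maximal: list[str] = []
    for s in uniq:
        if not any(len(t) > len(s) and contains(t, s) for t in uniq):
            maximal.append(s)

    rep_of_seq: dict[str, str] = {}
    for s in uniq:
        if s in set(maximal):
            rep_of_seq[s] = seq_to_ids[s][0]
        else:
            # candidates sorted longest-first then by representative id
            cands = [t for t in maximal if contains(t, s)]
            best = min(cands, key=lambda t: (-len(t), seq_to_ids[t][0]))
            rep_of_seq[s] = seq_to_ids[best][0]

    groups: dict[str, set[str]] = {}
    for asv, s in seqs.items():
        groups.setdefault(rep_of_seq[s], set()).add(asv)

    reps = sorted(groups)
    merged = pd.DataFrame(
        {rep: table.counts[sorted(groups[rep])].sum(axis=1) for rep in reps},
        index=table.counts.index,
    )
    merged_seqs = {rep: seqs[rep] for rep in reps}
    mm = MergeMap({rep: frozenset(g) for rep, g in groups.items()})
    return AsvCountTable(counts=merged, sequences=merged_seqs), mm


# -- rarefaction -----------------------------------------------------------


def rarefy(table: AsvCountTable, depth: int = 1000, seed: int | None = None) -> AsvCountTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped, as are ASV
    columns left all-zero afterwards.  Sampling is multivariate
    hypergeometric (classic rarefaction); ``seed`` makes it reproducible.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if table.counts.empty:
        raise ValueError("empty count table")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = totals[totals >= depth].index
    rows = []
    for sid in keep:
        row = table.counts.loc[sid].to_numpy()
        if row.sum() == depth:
            rows.append(row)
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth))
    out = pd.DataFrame(rows, index=list(keep), columns=table.counts.columns, dtype=np.int64)
    out = out.loc[:, out.sum(axis=0) > 0]
    seqs = None
    if table.sequences is not None:
        seqs = {a: table.sequences[a] for a in out.columns}
    return AsvCountTable(counts=out, sequences=seqs)


# -- prevalence ------------------------------------------------------------

SampleFilter = Callable[[pd.DataFrame], pd.Series] | Sequence[str] | pd.Series


def _select_samples(
    table_index: pd.Index, metadata: pd.DataFrame, sample_filter: SampleFilter | None
) -> list[str]:
    if sample_filter is None:
        sel = [s for s in table_index if s in metadata.index]
    elif callable(sample_filter):
        mask = sample_filter(metadata)
        sel = [s for s in table_index if s in metadata.index[mask]]
    elif isinstance(sample_filter, pd.Series):
        sel = [s for s in table_index if s in metadata.index[sample_filter.astype(bool)]]
    else:
        wanted = set(sample_filter)
        sel = [s for s in table_index if s in wanted]
    return sel


def asv_prevalence(
    table: AsvCountTable,
    metadata: pd.DataFrame,
    sample_filter: SampleFilter | None = None,
) -> dict[str, AsvPrevalence]:
    """Per-ASV prevalence over the selected samples.

    ``metadata`` is indexed by sample id and must carry a ``study`` column.
    Overall prevalence pools all selected samples; MSP takes the median of
    within-study prevalences over studies contributing at least one
    selected sample, which is robust to unequal study sizes.
    """
    selected = _select_samples(table.counts.index, metadata, sample_filter)
    if not selected:
        raise ValueError("sample filter selects no samples")
    sub = table.counts.loc[selected]
    present = sub > 0
    studies = metadata.loc[selected, "study"]
    per_study = present.groupby(studies).mean()  # studies x ASVs
    pos_by_study = present.groupby(studies).any()

    out: dict[str, AsvPrevalence] = {}
    overall = present.mean(axis=0)
    msp = per_study.median(axis=0)
    occ = pos_by_study.sum(axis=0)
    for asv in table.asv_ids:
        out[asv] = AsvPrevalence(
            overall_prevalence=float(overall[asv]),
            msp=float(msp[asv]),
            study_occurrence=int(occ[asv]),
        )
    return out
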