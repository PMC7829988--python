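"""Synthetic multi-study microbiome datasets with planted ground truth.

The generator emulates the statistical structure the core-clade analysis
assumes, without any sequence download: several studies of unequal size,
sparse over-dispersed ASV counts, a random phylogeny, a handful of planted
"core" clades whose member lineages occur at elevated prevalence across
samples, and exposure arms that shift affected clades' abundance by a known
log fold change.  Every dataset ships with a truth record so downstream
calls (core clades, sensitivity) can be scored for recovery.

Occupancy model: each tip is present in a sample independently with
probability ``core_occupancy`` (members of planted cores) or
``background_occupancy`` (everything else).  Conditional on presence, a
tip's expected count is its log-normal relative abundance, normalised
within the sample and scaled to the expected library size; realised counts
are negative-binomial (gamma-mixed Poisson) around that mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from . import phylo as _phylo
from .asv_table import AsvCountTable, write_fasta
from .phylo import Phylogeny

CONTROL = "control"

__all__ = [
    "ExposureSpec",
    "SimulationConfig",
    "TruthRecord",
    "simulate_tree",
    "simulate_dataset",
    "simulate_sequences",
    "inject_duplicate_sequences",
    "write_dataset",
]


@dataclass
class ExposureSpec:
    """One exposure arm: which study, which clades it perturbs, how much.

    ``affected_clade_ids`` may be left ``None`` to let the simulator pick
    ``n_affected`` planted core clades at random.
    """

    study: str
    label: str
    log_fold_change: float
    affected_clade_ids: Sequence[str] | None = None
    n_affected: int = 1


@dataclass
class SimulationConfig:
    n_tips: int = 100
    n_studies: int = 5
    samples_per_study: Sequence[int] = (40, 30, 24, 20, 16)
    depth_mean: float = 5000.0
    rarefaction_depth: int = 1000
    n_core_clades: int = 5
    core_occupancy: float = 0.9
    background_occupancy: float = 0.05
    abundance_logmean: float = 0.0
    abundance_logsd: float = 1.0
    exposures: Sequence[ExposureSpec] = ()
    nb_dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.background_occupancy <= 1 and 0 <= self.core_occupancy <= 1):
            raise ValueError("occupancies must lie in [0, 1]")
        if self.n_core_clades > 0 and self.core_occupancy <= self.background_occupancy:
            raise ValueError("core_occupancy must exceed background_occupancy")
        if len(self.samples_per_study) != self.n_studies:
            raise ValueError("samples_per_study must have length n_studies")
        if any(n < 2 for n in self.samples_per_study):
            raise ValueError("every study needs at least 2 samples")
        if self.n_tips < 3:
            raise ValueError("n_tips must be >= 3")

    @property
    def study_names(self) -> list[str]:
        return [f"study{i + 1}" for i in range(self.n_studies)]

    @classmethod
    def study_scale(cls, seed: int = 0) -> "SimulationConfig":
        """Desk-scale emulation of an integrated multi-study design.

        Eight studies of unequal size with nine exposure arms between them
        (two studies carry two arms each, one study is control-only), a
        2000-tip phylogeny so planted-core members stay a small fraction of
        all tips — the regime in which prevalent clades separate from the
        permutation null, as in real amplicon collections where most ASVs
        are rare — ten planted core clades, and clade-specific exposure
        effects of two- to four-fold in either direction.
        """
        exposures = [
            ExposureSpec("study1", "parasite", np.log(4), n_affected=3),
            ExposureSpec("study1", "bps", -np.log(4), n_affected=3),
            ExposureSpec("study2", "triclosan", -np.log(3), n_affected=2),
            ExposureSpec("study2", "bpa", np.log(3), n_affected=2),
            ExposureSpec("study3", "silver_np", -np.log(2), n_affected=2),
            # ethanol arm carries no true effect: a built-in null exposure
            ExposureSpec("study4", "ethanol", 0.0, n_affected=0),
            ExposureSpec("study5", "antibiotic", -np.log(4), n_affected=3),
            ExposureSpec("study6", "high_fat", np.log(2), n_affected=2),
            ExposureSpec("study7", "crowding", -np.log(2), n_affected=2),
        ]
        return cls(
            n_tips=2000,
            n_studies=8,
            samples_per_study=(60, 48, 40, 36, 32, 30, 28, 24),
            depth_mean=5000.0,
            rarefaction_depth=1000,
            n_core_clades=10,
            core_occupancy=0.9,
            background_occupancy=0.05,
            abundance_logmean=0.0,
            abundance_logsd=1.0,
            exposures=exposures,
            nb_dispersion=2.0,
            seed=seed,
        )


@dataclass
class TruthRecord:
    """Ground truth for a simulated dataset."""

    planted_core_clades: set[str]
    exposure_effects: dict[tuple[str, str, str], float]  # (study, label, clade) -> lfc
    tip_occupancy: dict[str, float]
    core_tips: set[str] = field(default_factory=set)

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_core_clades": sorted(self.planted_core_clades),
                "exposure_effects": [
                    {"study": s, "exposure": e, "clade_id": c, "log_fold_change": v}
                    for (s, e, c), v in sorted(self.exposure_effects.items())
                ],
                "tip_occupancy": dict(sorted(self.tip_occupancy.items())),
                "core_tips": sorted(self.core_tips),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        d = json.loads(text)
        return cls(
            planted_core_clades=set(d["planted_core_clades"]),
            exposure_effects={
                (e["study"], e["exposure"], e["clade_id"]): e["log_fold_change"]
                for e in d["exposure_effects"]
            },
            tip_occupancy=d["tip_occupancy"],
            core_tips=set(d.get("core_tips", [])),
        )


# -- tree simulation -------------------------------------------------------


def simulate_tree(n_tips: int, seed: int | None = None) -> Phylogeny:
    """Random rooted binary tree by sequential uniform pairwise joins.

    Starting from ``n_tips`` singleton lineages, two lineages are drawn
    uniformly at random and joined under a fresh parent until one remains;
    child branch lengths are exponential(1).  This yields exchangeable
    random topologies with strictly positive branch lengths.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    lineages: list[dendropy.Node] = []
    width = max(4, len(str(n_tips)))
    for i in range(n_tips):
        label = f"asv{i + 1:0{width}d}"
        node = dendropy.Node(taxon=dendropy.Taxon(label=label))
        taxa.add_taxon(node.taxon)
        lineages.append(node)
    while len(lineages) > 1:
        i, j = rng.choice(len(lineages), size=2, replace=False)
        i, j = sorted((int(i), int(j)))
        a, b = lineages[i], lineages[j]
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = float(rng.exponential(1.0))
        b.edge.length = float(rng.exponential(1.0))
        lineages = [n for k, n in enumerate(lineages) if k not in (i, j)]
        lineages.append(parent)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = lineages[0]
    tree.is_rooted = True
    return Phylogeny(tree)


# -- sequence simulation ---------------------------------------------------


def simulate_sequences(
    tip_labels: Sequence[str],
    seed: int | None = None,
    length_range: tuple[int, int] = (225, 254),
) -> dict[str, str]:
    """Random DNA per tip, lengths in the 16S amplicon range."""
    rng = np.random.default_rng(seed)
    out = {}
    for label in tip_labels:
        n = int(rng.integers(length_range[0], length_range[1] + 1))
        out[label] = "".join(rng.choice(list("ACGT"), size=n))
    return out


def inject_duplicate_sequences(
    fasta: dict[str, str],
    fraction: float,
    seed: int | None = None,
    min_substring: int = 40,
) -> tuple[dict[str, str], dict[str, set[str]]]:
    """Add exact-copy or contiguous-substring duplicates of existing records.

    ``round(fraction * n)`` records are injected, each derived from a
    uniformly chosen source; half are exact copies, half proper substrings
    (at least ``min_substring`` bp, redrawn if the fragment happens to occur
    in any other record, so the truth map stays unambiguous).  Returns the
    augmented record dict plus the expected merge groups keyed by
    representative id (source ids sort before their ``<src>dupNN``
    derivatives, so the source is always the representative).
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = dict(fasta)
    truth: dict[str, set[str]] = {k: {k} for k in fasta}
    names = sorted(fasta)
    n_inject = round(fraction * len(names))
    for k in range(n_inject):
        src = names[int(rng.integers(len(names)))]
        dup_id = f"{src}dup{k + 1:02d}"
        seq = fasta[src]
        if rng.random() < 0.5 or len(seq) <= min_substring:
            new_seq = seq
        else:
            new_seq = None
            for _ in range(100):
                ln = int(rng.integers(min_substring, len(seq)))
                start = int(rng.integers(0, len(seq) - ln + 1))
                cand = seq[start : start + ln]
                others = (s for i, s in fasta.items() if i != src)
                if not any(cand in s for s in others):
                    new_seq = cand
                    break
            if new_seq is None:  # pathological inputs; fall back to a copy
                new_seq = seq
        out[dup_id] = new_seq
        truth[src].add(dup_id)
    return out, truth


# -- full dataset ----------------------------------------------------------


def _eligible_core_nodes(
    tree: Phylogeny, min_tips: int = 2, max_tips: int = 10
) -> list[tuple[str, frozenset[str]]]:
    return [
        (c.clade_id, c.tip_set)
        for c in _phylo.enumerate_clades(tree, min_tips=min_tips)
        if min_tips <= c.n_tips <= max_tips
    ]


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[Phylogeny, AsvCountTable, pd.DataFrame, TruthRecord]:
    """Simulate tree, counts, metadata and truth under one config.

    Planted cores are disjoint internal clades of 2-10 tips (mimicking the
    recently diverged clades that dominate real core calls).  Exposure arms
    multiply affected clades' member-tip expected counts by
    ``exp(log_fold_change)`` after within-sample normalisation, so the
    effect is a clean multiplicative shift on clade abundance.  Metadata has
    exactly one ``control`` level per study.
    """
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config.n_tips, seed=int(rng.integers(2**31)))
    tips = tree.tip_labels

    # pick disjoint planted cores among small internal clades
    eligible = _eligible_core_nodes(tree)
    order = rng.permutation(len(eligible))
    planted: dict[str, frozenset[str]] = {}
    used: set[str] = set()
    for k in order:
        cid, tipset = eligible[int(k)]
        if used & tipset:
            continue
        planted[cid] = tipset
        used |= tipset
        if len(planted) >= config.n_core_clades:
            break
    if len(planted) < config.n_core_clades:
        raise ValueError(
            f"could only place {len(planted)} of {config.n_core_clades} disjoint "
            "core clades; use a larger tree or fewer cores"
        )
    core_tips = used

    # resolve exposures
    study_names = config.study_names
    effects: dict[tuple[str, str, str], float] = {}
    arm_effects: dict[tuple[str, str], dict[str, float]] = {}
    internal_ids = {c.clade_id for c in _phylo.enumerate_clades(tree, min_tips=1)}
    clade_tips = {c.clade_id: c.tip_set for c in _phylo.enumerate_clades(tree, min_tips=1)}
    planted_sorted = sorted(planted)
    for spec in config.exposures:
        if spec.study not in study_names:
            raise ValueError(f"exposure references unknown study {spec.study!r}")
        if spec.affected_clade_ids is not None:
            affected = list(spec.affected_clade_ids)
            unknown = set(affected) - internal_ids
            if unknown:
                raise ValueError(f"exposure references unknown clades {sorted(unknown)}")
        else:
            if spec.n_affected > len(planted_sorted):
                raise ValueError("n_affected exceeds number of planted cores")
            pick = rng.choice(len(planted_sorted), size=spec.n_affected, replace=False)
            affected = [planted_sorted[int(i)] for i in sorted(pick)]
        arm_effects[(spec.study, spec.label)] = {c: spec.log_fold_change for c in affected}
        for c in affected:
            effects[(spec.study, spec.label, c)] = spec.log_fold_change

    # sample sheet: per study, arms = control + that study's exposure labels
    rows = []
    for si, (study, n_samples) in enumerate(zip(study_names, config.samples_per_study)):
        labels = [CONTROL] + sorted(
            {s.label for s in config.exposures if s.study == study}
        )
        base, extra = divmod(n_samples, len(labels))
        sizes = [base + (1 if j < extra else 0) for j in range(len(labels))]
        j = 0
        for label, size in zip(labels, sizes):
            for _ in range(size):
                j += 1
                rows.append(
                    {
                        "sample_id": f"{study}_s{j:03d}",
                        "study": study,
                        "facility": f"facility{si % 3 + 1}",
                        "age_dpf": [30, 60, 90, 180, 270][si % 5],
                        "exposure": label,
                    }
                )
    metadata = pd.DataFrame(rows).set_index("sample_id")

    # per-tip baseline relative abundance (log-normal, fixed across samples)
    base_abund = rng.lognormal(
        mean=config.abundance_logmean, sigma=config.abundance_logsd, size=len(tips)
    )
    occupancy = {
        t: (config.core_occupancy if t in core_tips else config.background_occupancy)
        for t in tips
    }
    occ_vec = np.array([occupancy[t] for t in tips])

    counts = np.zeros((len(metadata), len(tips)), dtype=np.int64)
    tip_index = {t: i for i, t in enumerate(tips)}
    k_disp = config.nb_dispersion
    for r, (sid, meta_row) in enumerate(metadata.iterrows()):
        present = rng.random(len(tips)) < occ_vec
        if not present.any():
            continue
        rel = np.where(present, base_abund, 0.0)
        rel = rel / rel.sum()
        mu = rel * config.depth_mean
        arm = (meta_row["study"], meta_row["exposure"])
        for cid, lfc in arm_effects.get(arm, {}).items():
            for t in clade_tips[cid]:
                mu[tip_index[t]] *= np.exp(lfc)
        lam = np.where(
            mu > 0, rng.gamma(shape=k_disp, scale=np.maximum(mu, 1e-12) / k_disp), 0.0
        )
        counts[r] = rng.poisson(lam)

    table = AsvCountTable(
        counts=pd.DataFrame(counts, index=metadata.index, columns=tips),
        sequences=simulate_sequences(tips, seed=int(rng.integers(2**31))),
    )
    truth = TruthRecord(
        planted_core_clades=set(planted),
        exposure_effects=effects,
        tip_occupancy=occupancy,
        core_tips=set(core_tips),
    )
    return tree, table, metadata, truth


def score_core_recovery(
    truth: TruthRecord,
    original_tree: Phylogeny,
    core_results,
    analysis_tree: Phylogeny,
) -> dict[str, float]:
    """Score called core clades against the planted truth.

    Planted clades are matched to analysis-tree clades by tip set
    (intersected with the tips that survived merging/rarefaction, since
    clade ids are renumbered when the tree is pruned).  Sensitivity is the
    fraction of planted clades recovered; the false-discovery proportion
    counts called clades containing *no* planted-core tip — ancestors of a
    planted clade genuinely are more prevalent than chance, so they are not
    false positives.
    """
    orig = {c.clade_id: c.tip_set for c in _phylo.enumerate_clades(original_tree)}
    surviving = set(analysis_tree.tip_labels)
    called = {
        c.clade_id: frozenset(c.tip_set) for c in _phylo.enumerate_clades(analysis_tree)
    }
    called_core = {r.clade_id for r in core_results if r.is_core}
    core_tipsets = {called[c] for c in called_core if c in called}
    recovered = sum(
        1
        for p in truth.planted_core_clades
        if frozenset(orig.get(p, frozenset()) & surviving) in core_tipsets
    )
    n_planted = len(truth.planted_core_clades)
    false_calls = sum(
        1 for c in called_core if c in called and not (called[c] & truth.core_tips)
    )
    return {
        "sensitivity": recovered / n_planted if n_planted else float("nan"),
        "fdp": false_calls / len(called_core) if called_core else 0.0,
        "n_called": float(len(called_core)),
        "n_planted": float(n_planted),
    }


def map_clade_ids(original_tree: Phylogeny, analysis_tree: Phylogeny) -> dict[str, str]:
    """Match clade ids across trees by (surviving) tip set.

    Pruning tips renumbers internal nodes, so truth recorded on the
    simulated tree must be carried over by tip-set identity.
    """
    surviving = set(analysis_tree.tip_labels)
    called = {
        frozenset(c.tip_set): c.clade_id for c in _phylo.enumerate_clades(analysis_tree)
    }
    out = {}
    for c in _phylo.enumerate_clades(original_tree):
        key = frozenset(c.tip_set & surviving)
        if key in called:
            out[c.clade_id] = called[key]
    return out


def score_sensitivity_calls(
    truth: TruthRecord,
    records,
    id_map: dict[str, str] | None = None,
) -> dict[str, float]:
    """Score exposure-sensitivity calls against the planted effects.

    A planted effect (study, exposure, clade) counts as detected when the
    matching record is flagged sensitive; planted effects on clades that
    never entered the scan (e.g. not called core) count as missed.

    Calls on unplanted clades within an *affected* arm are not scored as
    false: shifting one clade at a fixed rarefaction depth depresses every
    other clade (compositional spillover), and ancestors of an affected
    clade shift with it, so such calls can be genuine signal.  Calibration
    is instead measured on null arms — exposure levels with no planted
    effect at all — where every sensitive call is false by construction:
    ``null_arm_call_rate`` is the fraction of null-arm tests flagged
    sensitive (NaN when the design has no null arm).
    """
    id_map = id_map or {}
    sensitive = {
        (r.study, r.exposure_level, r.clade_id) for r in records if r.sensitive
    }
    truth_keys = {
        (s, e, id_map.get(c, c)) for (s, e, c) in truth.exposure_effects
    }
    detected = len(truth_keys & sensitive)
    n_truth = len(truth_keys)
    effect_arms = {(s, e) for (s, e, _) in truth.exposure_effects}
    null_tests = [
        r for r in records if (r.study, r.exposure_level) not in effect_arms
    ]
    null_calls = sum(1 for r in null_tests if r.sensitive)
    return {
        "sensitivity": detected / n_truth if n_truth else float("nan"),
        "null_arm_call_rate": (
            null_calls / len(null_tests) if null_tests else float("nan")
        ),
        "n_sensitive_calls": float(len(sensitive)),
        "n_planted_effects": float(n_truth),
    }


def write_dataset(
    outdir: str | Path,
    tree: Phylogeny,
    table: AsvCountTable,
    metadata: pd.DataFrame,
    truth: TruthRecord,
) -> None:
    """Emit tree.nwk, asvs.fasta, counts.tsv, metadata.tsv, truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _phylo.write_newick(tree, outdir / "tree.nwk")
    if table.sequences:
        write_fasta(table.sequences, outdir / "asvs.fasta")
    table.write_tsv(outdir / "counts.tsv")
    metadata.to_csv(outdir / "metadata.tsv", sep="\t")
    (outdir / "truth.json").write_text(truth.to_json())
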