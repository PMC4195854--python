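"""Scoring of simulation replicates: false positives, power, summaries.

A replicate record holds the inferred guide tree and the delimitation
posterior; scoring maps each within-species population pair (A1-A2, ...,
D1-D2) to the node of the *inferred* guide tree that separates it — the most
recent common ancestor of the pair — and counts a false positive when that
node's split posterior reaches the 0.95 threshold.  This reproduces the
"node 11" rule: on a wrong guide tree the pair may be separated by a deep
node, and splitting that node is what splits the pair.  Per-clade
distributions are summarised by median and quartiles (linear-interpolation
quantiles) and by histograms with 20 bins of width 0.05, the last bin
closed at 1.0 so that its count equals the false-positive count at the 0.95
threshold.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .delimit import RjmcmcConfig, SplitPosterior, rjmcmc_delimit
from .likelihood import PriorConfig
from .mlsearch import MlSearchConfig, ml_guide_tree
from .simulate import ReplicateConfig, simulate_replicate
from .sptree_mcmc import SpeciesTreeMcmcConfig, map_guide_tree, mcmc_species_tree
from .species_model import build_species_tree
from .trees import RootedTree, clades, parse_newick, write_newick

__all__ = ["ReplicateRecord", "StudyConfig", "StudySummary", "pair_node_posterior",
           "false_positive_rate", "summarize", "run_study", "correct_guide_tree",
           "PAIRS"]

PAIRS = [("A1", "A2"), ("B1", "B2"), ("C1", "C2"), ("D1", "D2")]

HIST_EDGES = np.linspace(0.0, 1.0, 21)


def correct_guide_tree(tree_id: int) -> RootedTree:
    """The correct 8-population guide tree implied by a species tree."""
    species = build_species_tree(tree_id, "low").tree
    newick = species.canonical_newick(lengths=False)
    for sp in "ABCD":
        newick = newick.replace(sp, f"({sp}1,{sp}2)")
    return parse_newick(newick)


def pair_node_posterior(guide: RootedTree, posterior: SplitPosterior,
                        pair: tuple[str, str]) -> float:
    """Split posterior of the node separating a population pair.

    The node is the MRCA of the pair on the (possibly wrong) guide tree;
    splitting it is what assigns the two populations to different species.
    """
    for tip in pair:
        if tip not in guide.tip_labels():
            raise ValueError(f"population {tip} not on the guide tree")
    clade = guide.clade(guide.mrca(pair))
    return posterior.split_prob[clade]


@dataclass
class ReplicateRecord:
    """Scores for one replicate under one guide-tree arm."""

    index: int
    seed: int
    arm: str                                  # "ml" | "sptree" | "true"
    guide_newick: str
    pair_posterior: dict = field(default_factory=dict)   # "A1A2" -> prob
    clade_posterior: dict = field(default_factory=dict)  # "AB"/"CD"/"ABC"/"ABCD" -> prob or None
    guide_has_clade: dict = field(default_factory=dict)  # clade tag -> bool
    failure: str | None = None

    def to_json(self) -> dict:
        return {
            "index": self.index, "seed": self.seed, "arm": self.arm,
            "guide_newick": self.guide_newick,
            "pair_posterior": self.pair_posterior,
            "clade_posterior": self.clade_posterior,
            "guide_has_clade": self.guide_has_clade,
            "failure": self.failure,
        }

    @classmethod
    def from_json(cls, d: dict) -> "ReplicateRecord":
        return cls(d["index"], d["seed"], d["arm"], d["guide_newick"],
                   d["pair_posterior"], d["clade_posterior"],
                   d["guide_has_clade"], d.get("failure"))


def false_positive_rate(records: list[ReplicateRecord],
                        threshold: float = 0.95) -> dict[str, float]:
    """Per-pair fraction of replicates whose pair posterior reaches the threshold."""
    if not records:
        raise ValueError("no records")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    out = {}
    for a, b in PAIRS:
        tag = a + b
        vals = [r.pair_posterior[tag] for r in records if tag in r.pair_posterior]
        if vals:
            out[tag] = float(np.mean([v >= threshold for v in vals]))
    return out


@dataclass
class StudySummary:
    """Aggregate results across replicates for one configuration and arm."""

    n_replicates: int
    config: dict
    recovery: dict          # clade tag -> fraction of guide trees containing it
    fp_rate: dict           # pair tag -> false-positive rate at the threshold
    fp_se: dict             # binomial standard errors
    medians: dict           # tag -> median posterior
    quartiles: dict         # tag -> (lower, upper)
    histograms: dict        # tag -> list of 20 counts

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tag, val in self.fp_rate.items():
            rows.append({"metric": "false_positive_rate", "clade": tag,
                         "value": val, "se": self.fp_se.get(tag)})
        for tag, val in self.recovery.items():
            rows.append({"metric": "guide_recovery", "clade": tag, "value": val,
                         "se": float(np.sqrt(val * (1 - val) / self.n_replicates))})
        for tag, val in self.medians.items():
            lo, hi = self.quartiles[tag]
            rows.append({"metric": "median_split_posterior", "clade": tag,
                         "value": val, "q1": lo, "q3": hi})
        return pd.DataFrame(rows)


def summarize(records: list[ReplicateRecord], threshold: float = 0.95,
              config: dict | None = None) -> StudySummary:
    """Medians, quartiles, histograms and rates across replicates."""
    if not records:
        raise ValueError("no records")
    ok = [r for r in records if r.failure is None]
    n = len(ok)
    fp = false_positive_rate(ok, threshold)
    fp_se = {t: float(np.sqrt(v * (1 - v) / n)) for t, v in fp.items()}
    medians, quartiles, histograms = {}, {}, {}
    tags = sorted({t for r in ok for t in (*r.pair_posterior, *r.clade_posterior)})
    for tag in tags:
        vals = [r.pair_posterior.get(tag, r.clade_posterior.get(tag)) for r in ok]
        vals = np.array([v for v in vals if v is not None], float)
        if not vals.size:
            continue
        medians[tag] = float(np.median(vals))
        quartiles[tag] = (float(np.percentile(vals, 25)),
                          float(np.percentile(vals, 75)))
        counts, _ = np.histogram(vals, bins=HIST_EDGES)
        histograms[tag] = counts.tolist()
    recovery = {}
    for tag in sorted({t for r in ok for t in r.guide_has_clade}):
        recovery[tag] = float(np.mean([r.guide_has_clade[tag] for r in ok
                                       if tag in r.guide_has_clade]))
    return StudySummary(n, config or {}, recovery, fp, fp_se,
                        medians, quartiles, histograms)


# ----------------------------------------------------------------------
# the study driver


@dataclass(frozen=True)
class StudyConfig:
    """One cell of the study design plus chain settings."""

    tree_id: int = 1
    rate: str = "low"
    n_per_population: int = 3
    n_nuclear_loci: int = 1
    arms: tuple = ("ml", "sptree")
    n_replicates: int = 100
    threshold: float = 0.95
    sptree_mcmc: SpeciesTreeMcmcConfig = SpeciesTreeMcmcConfig.scaled()
    rjmcmc: RjmcmcConfig = RjmcmcConfig.scaled()
    ml: MlSearchConfig = MlSearchConfig()
    delimit: bool = True

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        for arm in self.arms:
            if arm not in ("ml", "sptree", "true"):
                raise ValueError(f"unknown guide arm {arm!r}")


def _clade_tags(tree_id: int):
    """True-guide-tree clades scored in the study tables."""
    if tree_id == 1:
        return {"AB": frozenset(["A1", "A2", "B1", "B2"]),
                "ABC": frozenset(["A1", "A2", "B1", "B2", "C1", "C2"]),
                "ABCD": frozenset(["A1", "A2", "B1", "B2", "C1", "C2", "D1", "D2"])}
    return {"AB": frozenset(["A1", "A2", "B1", "B2"]),
            "CD": frozenset(["C1", "C2", "D1", "D2"]),
            "ABCD": frozenset(["A1", "A2", "B1", "B2", "C1", "C2", "D1", "D2"])}


def _score_arm(ds, guide: RootedTree, arm: str, cfg: StudyConfig,
               prior: PriorConfig, seed: int, index: int) -> ReplicateRecord:
    rec = ReplicateRecord(index, seed, arm, write_newick(guide, lengths=False))
    have = clades(guide)
    tags = _clade_tags(cfg.tree_id)
    pair_clades = {a + b: frozenset([a, b]) for a, b in PAIRS}
    for tag, cl in tags.items():
        rec.guide_has_clade[tag] = cl in have
    for tag, cl in pair_clades.items():
        rec.guide_has_clade[tag] = cl in have
    if cfg.delimit:
        post = rjmcmc_delimit(ds.nuclear_alignments, guide, ds.popmap, prior,
                              cfg.rjmcmc, seed)
        for pair in PAIRS:
            rec.pair_posterior[pair[0] + pair[1]] = pair_node_posterior(
                guide, post, pair)
        for tag, cl in tags.items():
            rec.clade_posterior[tag] = post.split_prob.get(cl)
    return rec


def run_study(cfg: StudyConfig, master_seed: int,
              out_dir: str | None = None) -> dict[str, StudySummary]:
    """Simulate-infer-delimit over replicates; one summary per guide arm.

    Fully reproducible from ``master_seed`` (replicate seeds are spawned from
    it).  Per-replicate failures are caught, recorded, and excluded from the
    summaries.  When ``out_dir`` is given, per-replicate JSON records and a
    TSV summary are persisted there.
    """
    prior = PriorConfig.for_rate(cfg.rate)
    records: dict[str, list[ReplicateRecord]] = {arm: [] for arm in cfg.arms}
    master = np.random.SeedSequence(master_seed)
    for index, ss in enumerate(master.spawn(cfg.n_replicates)):
        rng = np.random.default_rng(ss)
        seed = int(rng.integers(1, 2**31 - 1))
        ds = simulate_replicate(
            ReplicateConfig(cfg.tree_id, cfg.rate, cfg.n_per_population,
                            cfg.n_nuclear_loci), rng, seed=seed)
        for arm in cfg.arms:
            try:
                if arm == "ml":
                    guide = ml_guide_tree(ds.mito_alignment, ds.popmap, cfg.ml)
                elif arm == "sptree":
                    samples = mcmc_species_tree(ds.nuclear_alignments, ds.popmap,
                                                cfg.sptree_mcmc, seed)
                    guide = map_guide_tree(samples, cfg.sptree_mcmc.keep_last)
                else:
                    guide = correct_guide_tree(cfg.tree_id)
                rec = _score_arm(ds, guide, arm, cfg, prior, seed, index)
            except Exception as exc:  # failures are data, not crashes
                rec = ReplicateRecord(index, seed, arm, "", failure=repr(exc))
            records[arm].append(rec)

    cfg_echo = {"tree_id": cfg.tree_id, "rate": cfg.rate,
                "n_per_population": cfg.n_per_population,
                "n_nuclear_loci": cfg.n_nuclear_loci,
                "n_replicates": cfg.n_replicates, "master_seed": master_seed}
    summaries = {arm: summarize(recs, cfg.threshold, {**cfg_echo, "arm": arm})
                 for arm, recs in records.items()}
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        for arm, recs in records.items():
            with open(os.path.join(out_dir, f"records_{arm}.json"), "w") as fh:
                json.dump([r.to_json() for r in recs], fh, indent=0)
        frames = []
        for arm, summ in summaries.items():
            frame = summ.to_frame()
            frame.insert(0, "arm", arm)
            frames.append(frame)
        pd.concat(frames).to_csv(os.path.join(out_dir, "summary.tsv"),
                                 sep="\t", index=False)
        with open(os.path.join(out_dir, "config.json"), "w") as fh:
            json.dump(cfg_echo, fh, indent=1)
    return summaries
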