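"""End-to-end orchestration: simulate/load -> distances -> delimit -> compare
-> ordinate, with a congruence-table report (N_match / N_MOTU / match ratio
per method), a per-species status table, and a method-similarity PCoA.

A bypass mode (:func:`report_from_counts`) renders the congruence table
directly from printed counts, pinning the table arithmetic without any
sequence data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import abgd as abgd_mod
from . import asap as asap_mod
from . import ptp as ptp_mod
from . import tcs as tcs_mod
from . import threshold as threshold_mod
from .congruence import (
    congruence,
    match_ratio_from_counts,
    pairwise_similarity,
    round_half_even,
    universal_match_count,
)
from .dataio import (
    Alignment,
    DistanceMatrix,
    Partition,
    PhyloTree,
    check_same_domain,
    read_fasta,
    read_matrix,
    read_newick,
    read_partition,
    write_matrix,
    write_partition,
)
from .distances import DistanceModel, distance_matrix
from .errors import BarcodelimError, ConfigError
from .ordination import ordinate_methods
from .synthetic import CommunityConfig, simulate_community

DEFAULT_METHODS = ("threshold", "tcs", "abgd", "asap", "ptp_single", "ptp_multi")


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    Either ``simulate`` holds a :class:`CommunityConfig` (synthetic run) or
    the explicit input paths are set.  A seed is required whenever any
    stochastic stage (simulation, ASAP permutations) is enabled.
    """

    outdir: str = "barcodelim_out"
    seed: int = 0
    methods: Sequence[str] = DEFAULT_METHODS
    simulate: Optional[CommunityConfig] = None
    alignment_path: Optional[str] = None
    tree_path: Optional[str] = None
    matrix_path: Optional[str] = None
    reference_path: Optional[str] = None
    distance_model: str = "p"
    threshold: float = 0.022
    tcs_confidence: float = 0.95
    abgd: abgd_mod.ABGDConfig = field(default_factory=abgd_mod.ABGDConfig)
    asap_permutations: int = 999
    outgroup: Optional[str] = None
    intersect: bool = False

    def __post_init__(self):
        if not self.methods:
            raise ConfigError("at least one delimitation method must be enabled")
        unknown = set(self.methods) - set(DEFAULT_METHODS)
        if unknown:
            raise ConfigError(f"unknown methods: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = CommunityConfig(**raw["simulate"])
        if "abgd" in raw and raw["abgd"] is not None:
            raw["abgd"] = abgd_mod.ABGDConfig(**raw["abgd"])
        return cls(**raw)


def _digest(obj) -> str:
    if isinstance(obj, (str, Path)) and Path(obj).exists():
        data = Path(obj).read_bytes()
    else:
        data = repr(obj).encode()
    return hashlib.sha256(data).hexdigest()[:16]


def delimit_all(
    cfg: RunConfig,
    alignment: Optional[Alignment],
    dm: Optional[DistanceMatrix],
    tree: Optional[PhyloTree],
) -> Dict[str, Partition]:
    """Run every enabled delimitation method; stage errors name the stage."""
    partitions: Dict[str, Partition] = {}
    for method in cfg.methods:
        try:
            if method == "threshold":
                if dm is None:
                    raise ConfigError("threshold delimitation needs distances")
                partitions["BIN-proxy"] = threshold_mod.single_linkage_delimit(
                    dm, threshold_mod.ThresholdConfig(cfg.threshold)
                )
            elif method == "tcs":
                if alignment is None:
                    raise ConfigError("TCS needs an alignment")
                limit = tcs_mod.ParsimonyLimit(
                    confidence=cfg.tcs_confidence,
                    max_steps=tcs_mod.connection_limit(
                        alignment.length, cfg.tcs_confidence
                    ),
                )
                partitions["TCS"] = tcs_mod.tcs_delimit(alignment, limit)
            elif method == "abgd":
                if dm is None:
                    raise ConfigError("ABGD needs distances")
                results = abgd_mod.unique_partitions(
                    abgd_mod.abgd_delimit(dm, cfg.abgd)
                )
                for res in results:
                    partitions[f"ABGD-p{res.prior:.4g}"] = res.partition
            elif method == "asap":
                if dm is None:
                    raise ConfigError("ASAP needs distances")
                ranked = asap_mod.asap_delimit(
                    dm, R=cfg.asap_permutations, seed=cfg.seed
                )
                partitions["ASAP-1st"] = ranked[0].partition
                if len(ranked) > 1:
                    partitions["ASAP-2nd"] = ranked[1].partition
            elif method in {"ptp_single", "ptp_multi"}:
                if tree is None:
                    raise ConfigError("PTP needs a rooted tree")
                ptree = tree
                if cfg.outgroup and cfg.outgroup in tree.tip_labels:
                    ptree = tree.prune([cfg.outgroup])
                mode = "single" if method == "ptp_single" else "multi"
                name = "mlPTP" if mode == "single" else "mPTP"
                delim = ptp_mod.ptp_ml_search(ptree, mode=mode)
                partitions[name] = delim.to_partition()
        except BarcodelimError as exc:
            raise BarcodelimError(f"stage {method!r} failed: {exc}") from exc
    return partitions


def congruence_tables(
    reference: Partition, partitions: Mapping[str, Partition]
) -> Tuple[pd.DataFrame, pd.DataFrame, dict]:
    """(counts table, per-species status table, JSON-able summary)."""
    rows = {}
    statuses = {}
    for name, part in partitions.items():
        res = congruence(reference, part)
        rows[name] = {
            "N_match": res.n_match,
            "N_MOTU": res.n_a,
            "match_ratio": round_half_even(res.match_ratio, 2),
        }
        statuses[name] = res.per_label
    table = pd.DataFrame(rows).loc[["N_match", "N_MOTU", "match_ratio"]]
    status_df = pd.DataFrame(statuses)
    status_df.index.name = "reference_block"
    universal = universal_match_count(reference, list(partitions.values()))
    summary = {
        "n_morph": reference.n_blocks,
        "universal_matches": universal,
        "methods": {
            name: {
                "n_match": int(rows[name]["N_match"]),
                "n_motu": int(rows[name]["N_MOTU"]),
                "match_ratio": float(
                    2 * rows[name]["N_match"]
                    / (rows[name]["N_MOTU"] + reference.n_blocks)
                ),
            }
            for name in rows
        },
    }
    return table, status_df, summary


def report_from_counts(
    counts: Mapping[str, Tuple[int, int]], n_morph: int
) -> pd.DataFrame:
    """Congruence table straight from (N_match, N_MOTU) counts per method."""
    rows = {}
    for name, (n_match, n_motu) in counts.items():
        ratio = match_ratio_from_counts(n_match, n_motu, n_morph)
        rows[name] = {
            "N_match": n_match,
            "N_MOTU": n_motu,
            "match_ratio": round_half_even(ratio, 2),
            "match_ratio_full": ratio,
        }
    return pd.DataFrame(rows).loc[
        ["N_match", "N_MOTU", "match_ratio", "match_ratio_full"]
    ]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow and write the report bundle to cfg.outdir."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": cfg.seed, "stages": [], "inputs": {}}

    alignment = tree = reference = dm = None
    if cfg.simulate is not None:
        community = simulate_community(cfg.simulate)
        community.write(outdir / "simulated")
        alignment = community.alignment
        tree = community.genealogy
        reference = community.true_partition
        log["inputs"]["simulation"] = _digest(cfg.simulate)
        log["stages"].append("simulate")
    else:
        if cfg.alignment_path:
            alignment = read_fasta(cfg.alignment_path)
            log["inputs"]["alignment"] = _digest(cfg.alignment_path)
        if cfg.tree_path:
            tree = read_newick(cfg.tree_path)
            log["inputs"]["tree"] = _digest(cfg.tree_path)
        if cfg.matrix_path:
            dm = read_matrix(cfg.matrix_path)
            log["inputs"]["matrix"] = _digest(cfg.matrix_path)
        if cfg.reference_path:
            reference = read_partition(cfg.reference_path)
            log["inputs"]["reference"] = _digest(cfg.reference_path)

    if dm is None and alignment is not None:
        dm = distance_matrix(alignment, DistanceModel(cfg.distance_model))
        write_matrix(dm, outdir / "distances.tsv")
        log["stages"].append("dist")

    domains = [d for d in (
        alignment.ids if alignment else None,
        dm.ids if dm else None,
        tree.tip_labels if tree else None,
        reference.domain if reference else None,
    ) if d is not None]
    if len(domains) > 1:
        common = check_same_domain(*domains, intersect=cfg.intersect)
        if cfg.intersect:
            ids = sorted(common)
            if alignment is not None:
                alignment = alignment.subset(ids)
            if dm is not None:
                dm = dm.submatrix(ids)
            if tree is not None:
                tree = tree.prune(tree.tip_labels - common)
            if reference is not None:
                reference = reference.restrict(ids)

    partitions = delimit_all(cfg, alignment, dm, tree)
    for name, part in partitions.items():
        write_partition(part, outdir / f"partition_{name.replace('/', '_')}.tsv")
    log["stages"].append("delimit")

    result: dict = {"partitions": partitions, "log": log}
    if reference is not None:
        table, status_df, summary = congruence_tables(reference, partitions)
        table.to_csv(outdir / "congruence_table.tsv", sep="\t")
        status_df.to_csv(outdir / "species_status.tsv", sep="\t")
        with open(outdir / "congruence.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        result.update(table=table, status=status_df, summary=summary)
        log["stages"].append("compare")

        all_parts = {"morphospecies": reference, **partitions}
        if len(all_parts) >= 3:
            sim = pairwise_similarity(all_parts)
            pd.DataFrame(
                sim.values, index=sim.methods, columns=sim.methods
            ).to_csv(outdir / "similarity.tsv", sep="\t")
            pcoa_res = ordinate_methods(all_parts)
            coords = pd.DataFrame(
                pcoa_res.coordinates,
                index=pcoa_res.names,
                columns=[f"axis{k + 1}" for k in range(pcoa_res.coordinates.shape[1])],
            )
            coords.to_csv(outdir / "pcoa.tsv", sep="\t")
            with open(outdir / "pcoa_eigen.json", "w") as fh:
                json.dump(
                    {
                        "eigenvalues": pcoa_res.eigenvalues.tolist(),
                        "proportion_explained": pcoa_res.proportion_explained.tolist(),
                        "negative_eigenvalues": pcoa_res.negative_eigenvalues.tolist(),
                    },
                    fh, indent=2,
                )
                fh.write("\n")
            result.update(similarity=sim, pcoa=pcoa_res)
            log["stages"].append("ordinate")

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return result
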