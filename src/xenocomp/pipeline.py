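"""Orchestration: run the enabled analysis stages and emit a report bundle.

The bundle mirrors the study's result sections: a per-operon KL table
(tetra/codon), alien-region calls from the windowed scan (BED), per-gene
NJ trees (newick), a pairwise incongruence table, a lineage-rate table and
a primer-coverage table — plus a config echo, a MANIFEST of stage statuses
and a run log.  All tables are TSV; the run is deterministic for a fixed
config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import divergence, genome_io, phylo, primers as primers_mod

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """One or more enabled stages failed; see the MANIFEST."""


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    # inputs
    genomes_fasta: str | None = None
    loci_tsv: str | None = None
    cds_tsv: str | None = None
    alignments: list[str] = field(default_factory=list)  # gene order C, A, B
    primers_tsv: str | None = None
    targets_fasta: str | None = None
    groups_tsv: str | None = None
    focal: list[str] = field(default_factory=list)
    outgroup: list[str] = field(default_factory=list)
    # stage toggles
    tetra: bool = False
    codon: bool = False
    scan: bool = False
    trees: bool = False
    rates: bool = False
    primers: bool = False
    # numeric parameters
    window: int = 2500
    step: int = 500
    kmin: int = 2
    kmax: int = 8
    pseudocount: float = 1.0
    min_len: int = 910
    max_mm: int = 2
    concat: bool = False

    def __post_init__(self) -> None:
        if not (2 <= self.kmin <= self.kmax <= 8):
            raise ValueError("k range must satisfy 2 <= kmin <= kmax <= 8")
        if self.window < 100 or self.step < 1:
            raise ValueError("window must be >= 100 and step >= 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.max_mm < 0 or self.min_len < 0:
            raise ValueError("max_mm and min_len must be non-negative")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls(**data)

    def enabled_stages(self) -> list[str]:
        return [
            s
            for s in ("tetra", "codon", "scan", "trees", "rates", "primers")
            if getattr(self, s)
        ]


def run_full(config: RunConfig) -> dict[str, str]:
    """Run every enabled stage; returns {stage: "ok" | error message}.

    Partial outputs are retained on failure; a MANIFEST.tsv marks stage
    statuses and a :class:`PipelineError` is raised if any stage failed.
    """
    stages = config.enabled_stages()
    if not stages:
        raise ValueError("no stages enabled in config")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("xenocomp")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    with open(out / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2)

    genomes = loci = cds_map = None
    if config.genomes_fasta:
        genomes = genome_io.read_fasta(config.genomes_fasta)
        logger.info("loaded %d genome(s) from %s", len(genomes), config.genomes_fasta)
    if config.loci_tsv:
        loci = genome_io.read_loci_tsv(config.loci_tsv)
        logger.info("loaded %d operon locus/loci", len(loci))
    if config.cds_tsv:
        cds_map = genome_io.read_cds_tsv(config.cds_tsv)
        if genomes:
            for g in genomes:
                g.features = cds_map.get(g.id, [])
                g.validate_features()

    status: dict[str, str] = {}

    def run_stage(name, fn) -> None:
        try:
            fn()
            status[name] = "ok"
            logger.info("stage %s: ok", name)
        except Exception as exc:  # noqa: BLE001 — stage isolation is the point
            status[name] = f"failed: {exc}"
            logger.error("stage %s failed: %s", name, exc)

    kl_methods = [m for m in ("tetra", "codon") if getattr(config, m)]
    if kl_methods:

        def _kl() -> None:
            if genomes is None or loci is None:
                raise ValueError("kl stages need genomes_fasta and loci_tsv")
            table = divergence.operon_kl_table(
                genomes, loci, methods=kl_methods, pseudocount=config.pseudocount
            )
            table.to_csv(out / "kl_table.tsv", sep="\t", index=False)
            logger.info("kl_table: %d rows", len(table))

        run_stage("+".join(kl_methods), _kl)

    if config.scan:

        def _scan() -> None:
            if genomes is None:
                raise ValueError("scan stage needs genomes_fasta")
            for g in genomes:
                scores = divergence.window_scan(
                    g,
                    window=config.window,
                    step=config.step,
                    k_range=(config.kmin, config.kmax),
                    pseudocount=config.pseudocount,
                )
                calls = divergence.call_alien_regions(
                    scores, [l for l in (loci or []) if l.genome_id == g.id]
                )
                divergence.calls_to_bed(calls, g.id, out / f"alien_calls_{g.id}.bed")
                pd.DataFrame(
                    {
                        "start": [s.start for s in scores],
                        "end": [s.end for s in scores],
                        "combined_kl": [s.combined_kl for s in scores],
                    }
                ).to_csv(out / f"window_scores_{g.id}.tsv", sep="\t", index=False)
                logger.info("scan %s: %d windows, %d calls", g.id, len(scores), len(calls))

        run_stage("scan", _scan)

    gene_trees: list[phylo.GeneTree] = []
    gene_names: list[str] = []
    if config.trees or config.rates:

        def _trees() -> None:
            if not config.alignments:
                raise ValueError("trees stage needs alignments")
            parts = [phylo.read_alignment_fasta(p) for p in config.alignments]
            for path, aln in zip(config.alignments, parts):
                name = Path(path).stem
                tree = phylo.nj_tree(phylo.poisson_distance(aln))
                gene_trees.append(tree)
                gene_names.append(name)
                with open(out / f"{name}.nwk", "w") as fh:
                    fh.write(tree.to_newick() + "\n")
            if config.concat:
                cat = phylo.concat_alignment(parts, min_len=config.min_len)
                tree = phylo.nj_tree(phylo.poisson_distance(cat))
                with open(out / "concat.nwk", "w") as fh:
                    fh.write(tree.to_newick() + "\n")
            if len(gene_trees) >= 2:
                rows = []
                for i in range(len(gene_trees)):
                    for j in range(i + 1, len(gene_trees)):
                        rep = phylo.rf_distance(
                            gene_trees[i], gene_trees[j],
                            labels=(gene_names[i], gene_names[j]),
                        )
                        rows.append(
                            {
                                "gene_a": rep.pair[0],
                                "gene_b": rep.pair[1],
                                "n_shared": rep.n_shared,
                                "rf": rep.rf,
                                "rf_normalized": rep.rf_normalized,
                            }
                        )
                pd.DataFrame(rows).to_csv(out / "incongruence.tsv", sep="\t", index=False)

        run_stage("trees", _trees)

    if config.rates:

        def _rates() -> None:
            if not gene_trees:
                raise ValueError("rates stage needs gene trees (enable trees stage)")
            if not config.focal or not config.outgroup:
                raise ValueError("rates stage needs focal and outgroup leaf lists")
            rows = []
            for name, tree in zip(gene_names, gene_trees):
                rep = phylo.rate_ratio(tree, config.focal, config.outgroup)
                rows.append(
                    {
                        "gene": name,
                        "rate_ratio": rep.rate_ratio,
                        "focal_mean_depth": rep.focal_mean_depth,
                        "background_mean_depth": rep.background_mean_depth,
                    }
                )
            pd.DataFrame(rows).to_csv(out / "rates.tsv", sep="\t", index=False)

        run_stage("rates", _rates)

    if config.primers:

        def _primers() -> None:
            if not (config.primers_tsv and config.targets_fasta and config.groups_tsv):
                raise ValueError(
                    "primers stage needs primers_tsv, targets_fasta and groups_tsv"
                )
            specs = primers_mod.read_primers_tsv(config.primers_tsv)
            fwd = [p for p in specs if p.role == "forward"]
            rev = [p for p in specs if p.role == "reverse"]
            pairs = [(f, r) for f in fwd for r in rev]
            targets = [
                (g.id, g.sequence) for g in genome_io.read_fasta(config.targets_fasta)
            ]
            gdf = pd.read_csv(config.groups_tsv, sep="\t")
            groups = dict(zip(gdf["target_id"].astype(str), gdf["group"].astype(str)))
            table = primers_mod.coverage_table(pairs, targets, groups, config.max_mm)
            table.to_csv(out / "primer_coverage.tsv", sep="\t", index=False)

        run_stage("primers", _primers)

    manifest = pd.DataFrame(
        sorted(status.items()), columns=["stage", "status"]
    )
    manifest.to_csv(out / "MANIFEST.tsv", sep="\t", index=False)
    root.removeHandler(handler)
    handler.close()

    failed = [s for s, st in status.items() if st != "ok"]
    if failed:
        raise PipelineError(f"stages failed: {failed}; see {out / 'MANIFEST.tsv'}")
    return status


def summarize_groups(
    kl_table: pd.DataFrame, group_labels: dict[str, str]
) -> pd.DataFrame:
    """Per group × method KL summary (n, mean, min, max), sorted by mean
    descending — the high-vs-low contrast across taxonomic/functional
    groups of operons."""
    if kl_table.empty:
        return pd.DataFrame(
            columns=["group", "method", "n", "mean_kl", "min_kl", "max_kl"]
        )
    unlabeled = sorted(set(kl_table["operon_id"]) - set(group_labels))
    if unlabeled:
        raise ValueError(f"operons without group labels: {unlabeled}")
    df = kl_table.assign(group=kl_table["operon_id"].map(group_labels))
    rows = []
    for (group, method), grp in df.groupby(["group", "method"]):
        rows.append(
            {
                "group": group,
                "method": method,
                "n": len(grp),
                "mean_kl": grp["kl_nats"].mean(),
                "min_kl": grp["kl_nats"].min(),
                "max_kl": grp["kl_nats"].max(),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["mean_kl"], ascending=False)
        .reset_index(drop=True)
    )
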