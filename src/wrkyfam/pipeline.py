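"""End-to-end orchestration with validated configuration and JSON reports."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import expression as expr_mod
from .classify import (ReferenceSet, classify_family, members_from_table1,
                       summarize_family)
from .domain_scan import DEFAULT_VARIANTS, PatternSpace
from .errors import ConfigError, FormatError
from .homology import homolog_groups, aggregate_pair_totals
from .io_formats import read_fasta, read_species_map
from .seq_characterize import (exon_intron_summary, physchem_profile,
                               scan_cis_elements)


@dataclass
class PipelineConfig:
    """Validated configuration shared by the pipeline subcommands."""

    fasta: str | None = None
    gff3: str | None = None
    promoters: str | None = None
    counts: str | None = None
    lengths: str | None = None
    ct_table: str | None = None
    candidates: str | None = None
    species_map: str | None = None
    references: str | None = None        # FASTA of labeled reference domains
    reference_labels: str | None = None  # TSV id -> label
    profile: str = "default"             # PatternSpace profile
    variants: tuple[str, ...] = tuple(sorted(DEFAULT_VARIANTS))
    inflation: float = 1.5
    cutoff: float = 0.3
    calibrator: str = "control"
    bootstrap: int = 100
    seed: int = 0
    out_dir: str = "wrkyfam_out"

    def __post_init__(self):
        if self.profile not in {"default", "strict"}:
            raise ConfigError(f"unknown pattern profile {self.profile!r}")
        if self.inflation <= 1:
            raise ConfigError("inflation must be > 1")
        if not 0 < self.cutoff <= 1:
            raise ConfigError("cutoff must be in (0, 1]")

    @property
    def pattern_space(self) -> PatternSpace:
        return PatternSpace.strict() if self.profile == "strict" else PatternSpace()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        if "variants" in data:
            data["variants"] = tuple(data["variants"])
        return cls(**data)

    def config_hash(self) -> str:
        # out_dir does not affect the computation, only where results land
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    def require(self, *names: str) -> None:
        for name in names:
            value = getattr(self, name)
            if value is None:
                raise ConfigError(f"config is missing required input {name!r}")
            if not Path(value).exists():
                raise ConfigError(f"{name} file not found: {value}")


def _load_references(config: PipelineConfig) -> ReferenceSet:
    config.require("references", "reference_labels")
    seqs = {r.id: r.sequence for r in read_fasta(config.references)}
    labels = read_species_map(config.reference_labels)  # id -> label TSV
    missing = set(seqs) - set(labels)
    if missing:
        raise ConfigError(f"references without labels: {sorted(missing)}")
    return ReferenceSet(entries=tuple(
        (rid, labels[rid], seq) for rid, seq in seqs.items()))


def run_identify(config: PipelineConfig) -> dict:
    """scan -> classify -> characterize; returns the JSON-ready report."""
    config.require("fasta")
    records = read_fasta(config.fasta)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                    "n_proteins": len(records)}
    if records:
        refs = _load_references(config)
        table = classify_family(records, refs,
                                pattern_space=config.pattern_space,
                                variant_set=frozenset(config.variants),
                                n_bootstrap=config.bootstrap, seed=config.seed)
        summary = summarize_family(table)
        table.to_dataframe().to_csv(out_dir / "family.tsv", sep="\t", index=False)
        profiles = pd.DataFrame(
            [{"gene_id": r.id, **vars(physchem_profile(r.sequence))}
             for r in records])
        profiles.to_csv(out_dir / "physchem.tsv", sep="\t", index=False)
        report.update({
            "group_counts": summary.group_counts,
            "variant_counts": summary.variant_counts,
            "length_min": summary.length_min,
            "length_max": summary.length_max,
            "length_mean": summary.length_mean,
            "records": table.to_dataframe().to_dict(orient="records"),
        })
    else:
        report.update({"group_counts": {}, "variant_counts": {},
                       "records": []})
    if config.gff3 is not None:
        from .io_formats import read_gff3_gene_models
        config.require("gff3")
        hist = exon_intron_summary(read_gff3_gene_models(config.gff3))
        report["intron_histogram"] = {str(k): v for k, v in sorted(hist.items())}
    if config.promoters is not None:
        config.require("promoters")
        from Bio import SeqIO  # promoters are nucleotide FASTA, read raw
        hits = {}
        for rec in SeqIO.parse(config.promoters, "fasta"):
            hits[rec.id] = len(scan_cis_elements(str(rec.seq)))
        report["cis_element_hits"] = hits
    with open(out_dir / "identify_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def run_homology(config: PipelineConfig) -> dict:
    config.require("fasta", "species_map")
    records = read_fasta(config.fasta)
    species = read_species_map(config.species_map)
    tagged = [type(r)(id=r.id, sequence=r.sequence,
                      species=species.get(r.id, ""))
              for r in records]
    result = homolog_groups(tagged, inflation=config.inflation,
                            cutoff=config.cutoff)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "clusters.tsv", "w") as fh:
        fh.write("cluster\tgene_id\n")
        for i, cluster in enumerate(result.clusters, start=1):
            for gid in sorted(cluster):
                fh.write(f"c{i}\t{gid}\n")
    pd.DataFrame([vars(p) for p in result.typed_pairs]).to_csv(
        out_dir / "pairs.tsv", sep="\t", index=False)
    result.pair_table.to_dataframe().to_csv(out_dir / "pairtable.tsv", sep="\t")
    paralog, ortholog, coortholog = aggregate_pair_totals(result.pair_table)
    report = {"config_hash": config.config_hash(), "seed": config.seed,
              "n_clusters": len(result.clusters),
              "paralog_pairs": paralog, "ortholog_pairs": ortholog,
              "coortholog_pairs": coortholog}
    with open(out_dir / "homology_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def run_expression(config: PipelineConfig) -> dict:
    config.require("counts", "lengths")
    counts = pd.read_csv(config.counts, sep="\t", index_col=0)
    lengths = pd.read_csv(config.lengths, sep="\t", index_col=0).iloc[:, 0]
    matrix = expr_mod.ExpressionMatrix(counts=counts, gene_lengths=lengths)
    abundance = expr_mod.rpkm_matrix(matrix)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    abundance.to_csv(out_dir / "rpkm.tsv", sep="\t")
    expr_mod.heatmap_export(abundance).to_csv(out_dir / "rpkm_log2.tsv", sep="\t")
    report: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                    "n_genes": int(abundance.shape[0]),
                    "n_samples": int(abundance.shape[1])}
    if config.ct_table is not None:
        config.require("ct_table")
        ct = pd.read_csv(config.ct_table, sep="\t")
        folds = expr_mod.ddct_fold_change(ct, calibrator=config.calibrator)
        folds.to_csv(out_dir / "folds.tsv", sep="\t", index=False)
        report["n_fold_changes"] = int(len(folds))
    if config.candidates is not None:
        config.require("candidates")
        cand = pd.read_csv(config.candidates, sep="\t")
        edges = expr_mod.coexpression_network(
            abundance, [tuple(r) for r in cand.itertuples(index=False)])
        pd.DataFrame([vars(e) for e in edges]).to_csv(
            out_dir / "network.tsv", sep="\t", index=False)
        report["sign_counts"] = expr_mod.network_sign_counts(edges)
    with open(out_dir / "expression_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
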