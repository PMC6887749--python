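"""End-to-end survey orchestration.

Stages run in order: identify -> characterize -> phylo -> structure /
duplication -> motifs / promoters (-> expression when tables are given).
Each stage writes its artifacts into the output directory and records the
thresholds in effect in a manifest, so every partition in the report is
auditable.  Reruns with an identical configuration are byte-identical:
all randomness flows from the configured seed and no timestamps are
written.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import (assign_names, assign_subfamilies, bootstrap_supports,
               characterization_report, chromosome_map, classify,
               compute_properties, detect_segmental, detect_tandem,
               extract_promoter, gene_structure_stats, identify_members,
               motif_width_stats, progressive_msa, read_fasta, read_gff3,
               read_motif_table, scan_cis_elements, scan_protein_motifs,
               write_fasta)
from .exceptions import ConfigError
from .expression import call_induced, fold_changes_from_ct
from .io import read_element_table
from .resources import default_cis_elements, default_motifs

ALL_STAGES = ("identify", "characterize", "phylo", "duplication",
              "motifs_promoters", "expression")


@dataclass
class SurveyConfig:
    genome: str = ""
    annotation: str = ""
    proteome: str = ""
    queries: str = ""
    motif_table: str = ""          # empty -> packaged 20-motif table
    elements: str = ""             # empty -> packaged starter dictionary
    outdir: str = "survey_out"
    naming_prefix: str = "SynABC"
    min_identity_pct: float = 30.0
    min_query_coverage: float = 0.5
    tandem_min_identity: float = 70.0
    segmental_min_identity: float = 80.0
    segmental_min_coverage: float = 0.5
    acidic_max: float = 6.5
    basic_min: float = 7.5
    bootstrap_replicates: int = 1000
    induction_threshold_fold: float = 2.0
    seed: int = 0
    ct_table: str = ""             # optional expression input
    per_species_counts: str = ""   # optional published-counts CSV

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SurveyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _require(config: SurveyConfig, *fields: str) -> None:
    for name in fields:
        value = getattr(config, name)
        if not value:
            raise ConfigError(f"config key {name!r} is required for this stage")
        if not Path(value).exists():
            raise ConfigError(f"config input {name}={value!r} does not exist")


class _Context(dict):
    """Stage workspace; loads prior-stage artifacts from disk when absent."""

    def __init__(self, config: SurveyConfig):
        super().__init__()
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)

    def members(self) -> dict[str, str]:
        if "members" not in self:
            path = self.outdir / "members.tsv"
            if not path.exists():
                raise ConfigError("members.tsv missing: run the identify stage first")
            df = pd.read_csv(path, sep="\t")
            self["members"] = dict(zip(df["gene_id"], df["family_name"]))
        return self["members"]

    def proteome(self) -> dict[str, str]:
        if "proteome" not in self:
            _require(self.config, "proteome")
            self["proteome"] = read_fasta(self.config.proteome)
        return self["proteome"]

    def models(self):
        if "models" not in self:
            _require(self.config, "annotation")
            self["models"] = read_gff3(self.config.annotation)
        return self["models"]


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_identify(ctx: _Context, report: dict) -> None:
    config = ctx.config
    _require(config, "queries", "proteome", "annotation")
    queries = read_fasta(config.queries)
    proteome = ctx.proteome()
    models = ctx.models()

    hits = identify_members(queries, proteome,
                            config.min_identity_pct, config.min_query_coverage)
    names = assign_names(hits.keys(), models, config.naming_prefix)
    ctx["members"] = names
    ctx["evidence"] = hits

    rows = []
    for gene_id, name in sorted(names.items(), key=lambda kv: kv[1]):
        aln, evidence = hits[gene_id]
        rows.append({
            "gene_id": gene_id, "family_name": name,
            "best_query": aln.query_id, "score": aln.score,
            "identity_pct": round(aln.identity_pct, 2),
            "query_coverage": round(aln.query_coverage, 3),
            "walker_a": f"{evidence.walker_a[0]}-{evidence.walker_a[1]}",
            "signature": f"{evidence.signature[0]}-{evidence.signature[1]}",
            "walker_b": f"{evidence.walker_b[0]}-{evidence.walker_b[1]}",
        })
    pd.DataFrame(rows).to_csv(ctx.outdir / "members.tsv", sep="\t", index=False)
    report["n_proteome"] = len(proteome)
    report["n_members"] = len(names)


def _stage_characterize(ctx: _Context, report: dict) -> None:
    config = ctx.config
    members = ctx.members()
    proteome = ctx.proteome()

    rows = []
    classifications = []
    for gene_id, name in sorted(members.items(), key=lambda kv: kv[1]):
        props = compute_properties(proteome[gene_id])
        cls = classify(props, config.acidic_max, config.basic_min)
        classifications.append(cls)
        formula = "".join(f"{el}{n}" for el, n in props.formula.items())
        rows.append({
            "gene_id": gene_id, "family_name": name,
            "length": props.length, "mw": round(props.mw, 2),
            "pi": round(props.pi, 2),
            "n_negative": props.n_negative, "n_positive": props.n_positive,
            "formula": formula,
            "instability_index": round(props.instability_index, 2),
            "aliphatic_index": round(props.aliphatic_index, 2),
            "gravy": round(props.gravy, 3),
            "n_tm_segments": len(props.tm_segments),
            "pi_class": cls.pi_class, "stability": cls.stability,
            "hydropathy": cls.hydropathy,
        })
    pd.DataFrame(rows).to_csv(ctx.outdir / "properties.tsv", sep="\t", index=False)
    report["classification_counts"] = characterization_report(classifications)
    # TM counts come from a hydropathy-window stand-in, not an HMM predictor
    report["tm_caller"] = "kyte-doolittle-window"


def _stage_phylo(ctx: _Context, report: dict) -> None:
    config = ctx.config
    members = ctx.members()
    proteome = ctx.proteome()
    queries = read_fasta(config.queries) if config.queries else {}

    seqs = {name: proteome[gene_id] for gene_id, name in members.items()}
    reference = {}
    for query_id, seq in queries.items():
        label = query_id
        seqs[label] = seq
        # reference leaves named Ref<subfamily> label their subtree
        reference[label] = query_id.removeprefix("Ref") or query_id
    if len(seqs) < 3:
        report["phylogeny"] = "skipped (fewer than 3 sequences)"
        return
    alignment = progressive_msa(seqs)
    write_fasta(alignment, ctx.outdir / "alignment.fasta")
    tree = bootstrap_supports(alignment, config.bootstrap_replicates,
                              seed=config.seed)
    (ctx.outdir / "tree.nwk").write_text(tree.to_newick(with_supports=True) + "\n")

    if reference:
        name_to_gene = {name: gid for gid, name in members.items()}
        assignments = assign_subfamilies(tree, reference)
        rows = [
            {"gene_id": name_to_gene[leaf], "family_name": leaf,
             "subfamily": subfam}
            for leaf, subfam in sorted(assignments.items())
            if leaf in name_to_gene
        ]
        pd.DataFrame(rows).to_csv(ctx.outdir / "subfamilies.tsv",
                                  sep="\t", index=False)
        sizes: dict[str, int] = {}
        for row in rows:
            sizes[row["subfamily"]] = sizes.get(row["subfamily"], 0) + 1
        report["subfamily_sizes"] = dict(sorted(sizes.items()))
        ctx["subfamilies"] = {row["gene_id"]: row["subfamily"] for row in rows}
    report["bootstrap_replicates"] = config.bootstrap_replicates


def _stage_duplication(ctx: _Context, report: dict) -> None:
    config = ctx.config
    members = ctx.members()
    models = ctx.models()
    proteome = ctx.proteome()
    by_id = {m.gene_id: m for m in models}

    intronless = set()
    structure_rows = []
    for gene_id, name in sorted(members.items(), key=lambda kv: kv[1]):
        n_exons, n_introns, is_intronless = gene_structure_stats(by_id[gene_id])
        if is_intronless:
            intronless.add(gene_id)
        structure_rows.append({
            "gene_id": gene_id, "family_name": name, "exons": n_exons,
            "introns": n_introns, "intronless": int(is_intronless),
        })
    pd.DataFrame(structure_rows).to_csv(ctx.outdir / "gene_structure.tsv",
                                        sep="\t", index=False)

    tandem = detect_tandem(members, models, proteome,
                           config.tandem_min_identity)
    segmental = detect_segmental(members, models, proteome,
                                 config.segmental_min_identity,
                                 config.segmental_min_coverage,
                                 tandem_pairs=tandem)
    rows = [
        {"gene_a": p.gene_a, "gene_b": p.gene_b, "mode": p.mode,
         "identity_pct": round(p.identity_pct, 2),
         "intervening": "" if p.intervening is None else p.intervening,
         "chromosome_a": p.chromosomes[0], "chromosome_b": p.chromosomes[1]}
        for p in tandem + segmental
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "mode", "identity_pct",
                                "intervening", "chromosome_a", "chromosome_b"]
                 ).to_csv(ctx.outdir / "duplications.tsv", sep="\t", index=False)
    chromosome_map(members, models).to_csv(ctx.outdir / "localization.tsv",
                                           sep="\t", index=False)
    ctx["tandem"] = tandem
    ctx["segmental"] = segmental
    ctx["intronless"] = intronless
    report["n_intronless"] = len(intronless)
    report["n_tandem_pairs"] = len(tandem)
    report["n_segmental_pairs"] = len(segmental)


def _stage_motifs_promoters(ctx: _Context, report: dict) -> None:
    config = ctx.config
    members = ctx.members()
    proteome = ctx.proteome()
    models = ctx.models()
    by_id = {m.gene_id: m for m in models}

    motifs = (read_motif_table(config.motif_table) if config.motif_table
              else default_motifs())
    count, min_w, max_w = motif_width_stats(motifs)
    report["motif_stats"] = {"count": count, "min_width": min_w,
                             "max_width": max_w}
    hit_rows = []
    for gene_id, name in sorted(members.items(), key=lambda kv: kv[1]):
        for hit in scan_protein_motifs(proteome[gene_id], motifs,
                                       protein_id=name):
            hit_rows.append({"gene_id": gene_id, "family_name": name,
                             "motif_id": hit.motif_id, "start": hit.start,
                             "mismatches": hit.mismatches})
    pd.DataFrame(hit_rows, columns=["gene_id", "family_name", "motif_id",
                                    "start", "mismatches"]
                 ).to_csv(ctx.outdir / "motif_hits.tsv", sep="\t", index=False)

    elements = (read_element_table(config.elements) if config.elements
                else default_cis_elements())
    _require(config, "genome")
    genome = read_fasta(config.genome)
    promoters = {}
    matrix_rows = []
    for gene_id, name in sorted(members.items(), key=lambda kv: kv[1]):
        record = extract_promoter(genome, by_id[gene_id])
        scan_cis_elements(record, elements)
        promoters[name] = record.sequence
        row: dict[str, Any] = {"gene_id": gene_id, "family_name": name}
        row.update(record.element_counts)
        matrix_rows.append(row)
    write_fasta(promoters, ctx.outdir / "promoters.fasta")
    columns = ["gene_id", "family_name"] + [e.name for e in elements]
    element_matrix = pd.DataFrame(matrix_rows, columns=columns).fillna(0)
    element_matrix.to_csv(ctx.outdir / "element_counts.tsv", sep="\t",
                          index=False)
    ctx["element_matrix"] = element_matrix
    report["n_promoters"] = len(promoters)


def _stage_expression(ctx: _Context, report: dict) -> None:
    config = ctx.config
    if not config.ct_table:
        return
    _require(config, "ct_table")
    ct = pd.read_csv(config.ct_table)
    folds = fold_changes_from_ct(ct)
    folds.to_csv(ctx.outdir / "fold_changes.tsv", sep="\t", index=False)
    profiles = call_induced(folds, config.induction_threshold_fold)
    rows = [
        {"gene": p.gene, "treatment": p.treatment,
         "induced": int(p.induced),
         "peak_timepoint": "" if p.peak_timepoint is None else p.peak_timepoint,
         "max_log2fc": round(max(p.log2fc), 3)}
        for p in profiles
    ]
    pd.DataFrame(rows).to_csv(ctx.outdir / "induction_calls.tsv", sep="\t",
                              index=False)
    report["n_induced"] = sum(r["induced"] for r in rows)
    report["induction_threshold_fold"] = config.induction_threshold_fold


_STAGE_FUNCTIONS = {
    "identify": _stage_identify,
    "characterize": _stage_characterize,
    "phylo": _stage_phylo,
    "duplication": _stage_duplication,
    "motifs_promoters": _stage_motifs_promoters,
    "expression": _stage_expression,
}


def run_survey(config: SurveyConfig,
               stages: tuple[str, ...] = ALL_STAGES) -> dict:
    """Run the requested stages in pipeline order and write the report.

    Returns the report dictionary (also written as JSON and text).
    """
    for stage in stages:
        if stage not in _STAGE_FUNCTIONS:
            raise ConfigError(f"unknown stage {stage!r}")
    ctx = _Context(config)
    report: dict[str, Any] = {"stages": list(stages)}

    if config.per_species_counts:
        _require(config, "per_species_counts")
        counts = pd.read_csv(config.per_species_counts)
        report["per_species_counts"] = dict(
            zip(counts.iloc[:, 0], (int(v) for v in counts.iloc[:, 1])))
        report["grand_total_members"] = int(counts.iloc[:, 1].sum())

    for stage in ALL_STAGES:
        if stage in stages:
            _STAGE_FUNCTIONS[stage](ctx, report)

    manifest = {"config": asdict(config), "stages": list(stages)}
    (ctx.outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    (ctx.outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
    (ctx.outdir / "report.txt").write_text(_format_report(report))
    return report


def _format_report(report: dict) -> str:
    lines = ["family survey report", "====================", ""]
    for key in sorted(report):
        value = report[key]
        if isinstance(value, dict):
            lines.append(f"{key}:")
            for sub, sub_value in sorted(value.items(), key=lambda kv: str(kv[0])):
                lines.append(f"  {sub}: {sub_value}")
        else:
            lines.append(f"{key}: {value}")
    return "\n".join(lines) + "\n"
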