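"""End-to-end orchestration of the three analyses over files.

Each runner reads its inputs, executes the stages in order, writes every
intermediate and a JSON MANIFEST of completed stages to the output
directory, and returns the final result object. All output headers carry the
tool version, a hash of the effective configuration, and the seed, so any
stage can be re-run independently from its files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .conservation import ConservationParams, conservation_profile
from .coevolution import RegionComparison, compare_regions
from .expression import (
    PartitionReport,
    RegulatorRule,
    classify_condition,
    directionality_analysis,
    intersect_targets,
)
from .io import (
    MultipleAlignment,
    alignment_from_records,
    read_alignment,
    read_de_table,
    read_fasta,
    read_metadata_keys,
    read_target_list,
    read_timecourse,
    write_alignment,
    write_tsv_with_header,
)
from .kinetics import calibrate_timecourse, fit_standard_curve, initial_rate, summarize_rates
from .orthologs import assign_one_to_one, deduplicate_strains, partition_by_partner


def config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _header(config: dict, seed) -> dict:
    return {
        "tool": f"coevkit {__version__}",
        "config_hash": config_hash(config),
        "seed": seed,
    }


def _write_manifest(outdir: Path, stages: list[str], config: dict, seed) -> None:
    manifest = {"completed_stages": stages, **_header(config, seed)}
    (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2) + "\n")


def run_coevolution(config: dict, outdir: str | Path) -> RegionComparison:
    """curate -> conserve (x2 sets) -> compare, from FASTA/TSV inputs.

    Required config keys: orthologs (FASTA), query (FASTA, 1 record),
    paralogs (FASTA), partner_organisms (TSV with an ``organism`` column),
    region (two-int list), seed. Optional: meta (species-key TSV),
    window_radius, permutations, no_weights.

    The partner-organism list is treated as authoritative for partner
    presence (absence of a listed organism means the partner ortholog could
    not be detected there); this assumption is recorded in output headers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []
    seed = int(config.get("seed", 0))
    hdr = _header(config, seed)
    hdr["partner_presence"] = "assumed authoritative from partner_organisms input"
    try:
        query = read_fasta(config["query"])[0]
        paralogs = read_fasta(config["paralogs"])
        records = read_fasta(config["orthologs"])
        if config.get("meta"):
            overrides = read_metadata_keys(config["meta"])
            for rec in records:
                if rec.id in overrides:
                    rec.species_key = overrides[rec.id]
        partner = set(
            pd.read_csv(config["partner_organisms"], sep="\t", comment="#")["organism"].astype(str)
        )

        cache: dict = {}
        deduped = deduplicate_strains(records, query, cache=cache)
        by_org = {rec.organism: [rec] for rec in deduped}
        assignments = assign_one_to_one(by_org, query, paralogs, cache=cache)
        partition = partition_by_partner(assignments, partner)
        rejection = pd.DataFrame(
            [(org, reason) for org, reason in sorted(partition.rejected.items())],
            columns=["organism", "reason"],
        )
        write_tsv_with_header(rejection, outdir / "rejections.tsv", hdr)
        stages.append("curate")

        params = ConservationParams(
            window_radius=int(config.get("window_radius", 3)),
            use_sequence_weighting=not config.get("no_weights", False),
        )
        alns = {}
        for name, organisms in (
            ("partner_positive", partition.partner_positive),
            ("partner_negative", partition.partner_negative),
        ):
            recs = [query] + [partition.assigned[o] for o in sorted(organisms)]
            aln = alignment_from_records(recs)
            write_alignment(aln, outdir / f"{name}.afa")
            prof = conservation_profile(aln, query.id, params)
            write_tsv_with_header(prof.to_frame(), outdir / f"profile_{name}.tsv", {**hdr, **asdict(params)})
            alns[name] = aln
        stages.append("conserve")

        region = tuple(int(x) for x in config.get("region", (336, 501)))
        comparison = compare_regions(
            alns["partner_positive"],
            alns["partner_negative"],
            query.id,
            region=region,
            params=params,
            n_permutations=int(config.get("permutations", 999)),
            seed=seed,
        )
        write_tsv_with_header(comparison.paired, outdir / "region_scores.tsv", hdr)
        summary = pd.DataFrame(
            [
                {
                    "region_start": region[0],
                    "region_end": region[1],
                    "delta_mean": comparison.delta_mean,
                    "permutation_p": comparison.permutation_p,
                    "signed_rank_p": comparison.signed_rank_p,
                    "n_permutations": comparison.n_permutations,
                }
            ]
        )
        write_tsv_with_header(summary, outdir / "comparison.tsv", hdr)
        stages.append("compare")
        return comparison
    finally:
        _write_manifest(outdir, stages, config, seed)


def run_expression(config: dict, outdir: str | Path) -> PartitionReport:
    """classify -> intersect -> directionality test, from DE/target TSVs.

    Required config keys: tables (list of {path, label}), targets (TSV),
    rules (list of {label, requirements: [[gene, direction, require_sig]]}).
    Optional: direction_class ("up"), min_class_size (6).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []
    seed = config.get("seed", "n/a")
    hdr = _header(config, seed)
    try:
        tables = [read_de_table(t["path"], t["label"]) for t in config["tables"]]
        targets = read_target_list(config["targets"])
        classifications = {}
        for table in tables:
            for rule_cfg in config.get("rules", []):
                rule = RegulatorRule(
                    label=rule_cfg["label"],
                    requirements=[tuple(r) for r in rule_cfg["requirements"]],
                )
                cls = classify_condition(table, rule)
                if cls.label != "unclassified":
                    classifications[table.condition_label] = cls.label
                    break
        stages.append("classify")

        shared = intersect_targets(
            tables,
            targets,
            direction_class=config.get("direction_class", "up"),
            min_class_size=int(config.get("min_class_size", 6)),
        )
        report = directionality_analysis(shared)
        stages.append("detest")

        write_tsv_with_header(report.per_gene, outdir / "per_gene_delta.tsv", hdr)
        summary = {
            "condition_classes": classifications,
            "n_shared": report.n_shared,
            "medians": report.medians,
            "up_counts": report.up_counts,
            "down_counts": report.down_counts,
            "rank_sum_p": report.rank_sum.p_value,
            "fisher_p": report.fisher.p_value,
            "excluded": report.excluded,
            **hdr,
        }
        (outdir / "report.json").write_text(json.dumps(summary, indent=2, default=str) + "\n")
        return report
    finally:
        _write_manifest(outdir, stages, config, seed)


def run_rates(config: dict, outdir: str | Path):
    """calibrate (optional) -> fit initial rates -> summarise, from CSV inputs.

    Required config keys: timecourse (CSV), control (condition label).
    Optional: standard_curve (CSV with concentration_um/reading columns),
    reading_kind, window_points, window_minutes, concentrations (dict).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []
    seed = config.get("seed", "n/a")
    hdr = _header(config, seed)
    try:
        kind = config.get("reading_kind", "concentration")
        courses = read_timecourse(config["timecourse"], reading_kind=kind)
        curve = None
        if config.get("standard_curve"):
            sc = pd.read_csv(config["standard_curve"], comment="#")
            curve = fit_standard_curve(sc["concentration_um"], sc["reading"])
            stages.append("standard_curve")
        if kind == "absorbance":
            if curve is None:
                raise ValueError("absorbance input requires a standard curve")
            courses = [calibrate_timecourse(tc, curve) for tc in courses]
            stages.append("calibrate")

        wp = config.get("window_points", 6)
        wm = config.get("window_minutes")
        slopes: dict[str, list[float]] = {}
        for tc in courses:
            slopes.setdefault(tc.condition, []).append(
                initial_rate(tc, window_points=wp, window_minutes=wm)
            )
        window_desc = f"time <= {wm} min" if wm is not None else f"first {wp} points"
        summary = summarize_rates(
            slopes,
            control=config["control"],
            concentrations=config.get("concentrations"),
            fit_window=window_desc,
        )
        stages.append("rates")

        rows = []
        for cond, res in summary.results.items():
            rows.append(
                {
                    "condition": cond,
                    "mean_rate_um_per_min": res.mean_rate,
                    "sd_rate": res.sd_rate,
                    "n_replicates": res.n_replicates,
                    "percent_inhibition": summary.percent_change.get(cond, 0.0),
                    "t_p_vs_control": summary.t_tests[cond].p_value
                    if cond in summary.t_tests
                    else float("nan"),
                }
            )
        write_tsv_with_header(pd.DataFrame(rows), outdir / "rates.tsv", hdr)
        return summary
    finally:
        _write_manifest(outdir, stages, config, seed)
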