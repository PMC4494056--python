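"""Pipeline orchestration: run the analysis stages over a config mapping.

Stages run in dependency order (classify first, rates last); each stage
writes one TSV into the output directory, a ``manifest.json`` records
completion state, and ``report.md`` renders summary tables with every
percentage recomputed from the underlying counts.  Identical config and
fixtures produce byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from . import archaic_conservation as arc
from . import creation_rates as cr
from . import domain_colocalization as dom
from . import hydroxymethyl_patterns as hmc
from . import lineage_specificity as lin
from . import proximity_enrichment as prox
from . import repeat_association as rep
from .core_genomics import (
    read_bed,
    read_chain,
    read_gene_table,
    read_methylation,
    read_repeatmasker,
    read_sites_bed,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "make_report"]

logger = logging.getLogger(__name__)

STAGES = ("classify", "repeats", "domains", "proximity", "hmc", "conserve", "rates")
_NEEDS_CLASSIFY = ("repeats", "domains", "proximity", "hmc", "conserve")

_KNOWN_TOP_KEYS = {"outdir", "seed", "inputs", "params", "stages", "rate_inputs"}
_KNOWN_PARAM_KEYS = {
    "min_match", "window_width", "proximity_threshold_bp",
    "colocalization_window_bp", "hmc_windows", "symbol_max_span",
    "archaic_individuals", "lad_fraction", "pmd_fraction",
}


class PipelineError(RuntimeError):
    pass


class PipelineConfig:
    """Validated pipeline configuration (from a YAML mapping or file)."""

    def __init__(self, mapping: Dict) -> None:
        unknown = set(mapping) - _KNOWN_TOP_KEYS
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        self.outdir = Path(mapping.get("outdir", "hsreg_out"))
        self.seed = int(mapping.get("seed", 0))
        self.inputs: Dict[str, object] = mapping.get("inputs", {})
        self.params: Dict[str, object] = mapping.get("params", {})
        unknown_params = set(self.params) - _KNOWN_PARAM_KEYS
        if unknown_params:
            raise PipelineError(f"unknown params: {sorted(unknown_params)}")
        self.stages: List[str] = list(mapping.get("stages", STAGES))
        for st in self.stages:
            if st not in STAGES:
                raise PipelineError(f"unknown stage {st!r}")
        self.rate_inputs = mapping.get("rate_inputs", "default")
        self._check_paths()

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def _check_paths(self) -> None:
        def check(value: object) -> None:
            if isinstance(value, str) and ("/" in value or value.endswith(
                    (".bed", ".tsv", ".chain", ".fa", ".yaml"))):
                if not Path(value).exists():
                    raise PipelineError(f"input path does not exist: {value}")
            elif isinstance(value, dict):
                for v in value.values():
                    check(v)

        check(self.inputs)

    def param(self, key: str, default):
        return self.params.get(key, default)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Execute the configured stages; returns the manifest mapping."""
    requested = [s for s in STAGES if s in config.stages]
    missing_upstream = [s for s in requested
                        if s in _NEEDS_CLASSIFY and "classify" not in requested]
    if missing_upstream:
        raise PipelineError(
            f"stages {missing_upstream} require the 'classify' stage, "
            "which is not enabled")

    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, object] = {"seed": config.seed, "stages": {}}
    min_match = float(config.param("min_match", 0.95))
    window_width = int(config.param("window_width", 200))

    classifications: Optional[List[lin.SiteClassification]] = None
    sites = None

    try:
        if "classify" in requested:
            sites = read_sites_bed(str(config.inputs["sites"]), window_width)
            panel = {}
            for species, spec in config.inputs["panel"].items():
                panel[species] = read_chain(str(spec["chain"]))
            alt = None
            if "alt_assembly_chain" in config.inputs:
                alt = read_chain(str(config.inputs["alt_assembly_chain"]))
            classifications = lin.classify_sites(sites, panel, alt, min_match)
            df = pd.DataFrame([{
                "site_id": c.site_id, "tf": c.tf, "label": c.label,
                "dual_assembly_unique": c.dual_assembly_unique,
            } for c in classifications])
            df.to_csv(out / "class.tsv", sep="\t", index=False)
            lin.classification_summary(classifications).to_csv(
                out / "class_summary.tsv", sep="\t", index=False)
            logger.info("classify: %d sites in, %d labeled", len(sites), len(df))
            manifest["stages"]["classify"] = {"n_sites": len(sites)}

        def human_specific_sites():
            return [c.site for c in classifications
                    if c.label == "human_specific" and c.site is not None]

        if "repeats" in requested:
            repeats = read_repeatmasker(str(config.inputs["repeats"]), dialect="bed")
            report = rep.annotate_repeat_overlap(human_specific_sites(), repeats)
            rows = []
            for tf, summary in rep.tabulate_families(report).items():
                rows.append({
                    "tf": tf, "n_sites": summary["n_sites"],
                    "n_in_repeats": summary["n_in_repeats"],
                    "pct_in_repeats": summary["pct_in_repeats"],
                    "n_in_ltr_line": summary["n_in_ltr_line"],
                    "pct_in_ltr_line": summary["pct_in_ltr_line"],
                    "family_counts": json.dumps(summary["family_counts"],
                                                 sort_keys=True),
                })
            pd.DataFrame(rows).to_csv(out / "repeats.tsv", sep="\t", index=False)
            manifest["stages"]["repeats"] = {"n_tfs": len(rows)}

        if "domains" in requested:
            lads = read_bed(str(config.inputs["lads"]))
            pmds = read_bed(str(config.inputs["pmds"]))
            rows = []
            for name, domains, frac_key in (("lads", lads, "lad_fraction"),
                                            ("pmds", pmds, "pmd_fraction")):
                domains.name = name
                fraction = config.param(frac_key, None)
                if fraction is None:
                    genome_len = max(iv.end for iv in domains)
                    domains.genome_size = {c: genome_len for c in domains.chromosomes}
                result = dom.place_in_domains(human_specific_sites(), domains,
                                              fraction=fraction)
                rows.append({
                    "domain_set": name, "n_sites": result.n_sites,
                    "n_inside": result.n_inside,
                    "expected_inside": round(result.expected_inside, 1),
                    "genome_fraction": round(result.genome_fraction, 4),
                    "p_binomial": result.p_binomial,
                })
            pd.DataFrame(rows).to_csv(out / "domains.tsv", sep="\t", index=False)
            manifest["stages"]["domains"] = {"n_domain_sets": len(rows)}

        if "proximity" in requested:
            genes = read_gene_table(str(config.inputs["genes"]))
            threshold = prox.ProximityThreshold(
                "coding", float(config.param("proximity_threshold_bp", 5000.0)))
            records, summary = prox.count_proximal(
                human_specific_sites(), genes, threshold)
            pd.DataFrame([{
                "gene_id": r.gene_id, "gene_class": r.gene_class,
                "ka_ks": r.ka_ks, "n_proximal_sites": r.n_proximal_sites,
            } for r in records]).to_csv(out / "proximity.tsv", sep="\t", index=False)
            manifest["stages"]["proximity"] = summary

        if "hmc" in requested:
            calls = read_methylation(str(config.inputs["methylation"]))
            windows = [int(x) for x in config.param("hmc_windows", [100, 1000])]
            results = hmc.hmc_proximity(human_specific_sites(), calls, windows)
            symbols = hmc.detect_symbols(
                calls, int(config.param("symbol_max_span", 50)))
            coloc = hmc.symbol_colocalization(human_specific_sites(), symbols)
            rows = [{
                "tf": r.tf, "window_bp": r.window_bp, "n_sites": r.n_sites,
                "n_with_hmc": r.n_with_hmc, "fraction": round(r.fraction, 4),
                "n_with_symbol": coloc.get(r.tf, {}).get("n_with_symbol"),
            } for r in results.values()]
            pd.DataFrame(rows).to_csv(out / "hmc_report.tsv", sep="\t", index=False)
            manifest["stages"]["hmc"] = {"n_symbols": len(symbols)}

        if "conserve" in requested:
            presence = pd.read_csv(str(config.inputs["presence"]), sep="\t",
                                   index_col="site_id")
            archaic = config.param(
                "archaic_individuals",
                [c for c in presence.columns if c.startswith("neand")])
            hs_ids = [c.site_id for c in classifications
                      if c.label == "human_specific"]
            hs_ids = [sid for sid in hs_ids if sid in presence.index]
            individuals = [
                arc.Individual(col,
                               arc.ERA_ARCHAIC if col in archaic else arc.ERA_MODERN,
                               presence_calls={
                                   sid: bool(presence.at[sid, col])
                                   for sid in hs_ids})
                for col in presence.columns]
            matrix = arc.score_conservation(hs_ids, {}, individuals)
            summary = arc.cohort_summary(matrix)
            era = arc.attribute_era(matrix)
            rows = [{"individual": iid, "era": e,
                     "conserved_pct": summary["per_individual_pct"][iid]}
                    for iid, e in matrix.individuals]
            pd.DataFrame(rows).to_csv(out / "conserve.tsv", sep="\t", index=False)
            manifest["stages"]["conserve"] = {
                "conserved_in_all_pct": summary["conserved_in_all_pct"],
                "n_post_split": era["n_post_split"],
                "n_assessable": era["n_assessable"],
            }

        if "rates" in requested:
            if config.rate_inputs == "default":
                inputs = cr.HESC_RATE_INPUTS
            else:
                inputs = [cr.LineageRateInput(**row) for row in config.rate_inputs]
            table = cr.build_rate_table(inputs)
            table.to_csv(out / "rates.tsv", sep="\t", index=False)
            manifest["stages"]["rates"] = {"n_rows": len(table)}
    except Exception:
        manifest["complete"] = False
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
        raise

    manifest["complete"] = True
    manifest["outputs"] = {
        p.name: _hash_file(p) for p in sorted(out.glob("*.tsv"))}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    make_report(out)
    return manifest


def _fmt_pct(count: int, total: int, dp: int = 1) -> str:
    return f"{round(100.0 * count / total, dp)}" if total else "0"


def make_report(outdir: Path) -> Path:
    """Render ``report.md`` from whatever stage TSVs are present.

    Percentages are recomputed from counts, never copied from stage
    output, so the report cross-checks the machine-readable tables.
    """
    outdir = Path(outdir)
    lines = ["# hsreg pipeline report", ""]

    def section(title: str, fname: str) -> Optional[pd.DataFrame]:
        path = outdir / fname
        lines.append(f"## {title}")
        if not path.exists():
            lines.append("_not run_\n")
            return None
        return pd.read_csv(path, sep="\t")

    df = section("Lineage classification", "class_summary.tsv")
    if df is not None:
        lines.append(df.to_string(index=False))
        lines.append("")

    df = section("Repeat association", "repeats.tsv")
    if df is not None:
        df = df.copy()
        df["pct_in_repeats"] = [
            _fmt_pct(k, n) for k, n in zip(df.n_in_repeats, df.n_sites)]
        lines.append(df.drop(columns=["family_counts"]).to_string(index=False))
        lines.append("")

    df = section("Domain colocalization", "domains.tsv")
    if df is not None:
        lines.append(df.to_string(index=False))
        lines.append("")

    df = section("Proximity placement", "proximity.tsv")
    if df is not None:
        n_assoc = int((df.n_proximal_sites >= 1).sum())
        lines.append(f"Associated genes: {n_assoc}/{len(df)} "
                     f"({_fmt_pct(n_assoc, len(df), 0)}%)\n")

    df = section("5hmC patterns", "hmc_report.tsv")
    if df is not None:
        lines.append(df.to_string(index=False))
        lines.append("")

    df = section("Individual-genome conservation", "conserve.tsv")
    if df is not None:
        lines.append(df.to_string(index=False))
        lines.append("")

    df = section("Creation rates", "rates.tsv")
    if df is not None:
        lines.append(df.to_string(index=False))
        lines.append("")

    path = outdir / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path
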