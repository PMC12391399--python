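"""End-to-end orchestration: read → log → center → scale → filter →
impute → DE → set overlap → GO summary → PCA, from a single config.

The run is deterministic given config + seed, writes every
intermediate table, and emits a machine-readable JSON report with
per-stage counts, DE summaries, Venn region counts, a checksum
manifest of every written file, and the full preprocessing provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import preprocess
from .annotation import summarize_go, write_go_summary
from .diffexpr import run_de_table, write_de_table
from .ordination import pca
from .set_analysis import extract_sets, write_region_report
from .tables_io import (read_design, read_go_map, read_protein_groups)

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("lfqpipe.pipeline")


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    protein_groups: str
    design: str
    out_dir: str
    go_map: str | None = None
    contrasts: list[str] = field(default_factory=list)  # isolates; empty = all
    log_base: float = 2.0
    center_stat: str = "mean"
    width_stat: str = "sd"
    min_valid_per_group: int = 2
    down_shift: float = 2.0
    impute_width: float = 0.3
    seed: int | None = None
    alpha_f: float = 0.05
    fc_threshold: float = 1.0
    p_threshold: float = 0.05
    strict: bool = True
    n_components: int = 2

    def validate(self) -> None:
        for name in ("protein_groups", "design"):
            p = getattr(self, name)
            if not Path(p).is_file():
                raise FileNotFoundError(f"config {name}: no such file {p!r}")
        if self.go_map is not None and not Path(self.go_map).is_file():
            raise FileNotFoundError(f"config go_map: no such file {self.go_map!r}")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run report (also written as
    ``report.json`` in the output directory).

    Any stage failure raises with the stage name prefixed, so callers
    (and the CLI) can abort with a precise diagnostic.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config), "stages": {}}
    written: list[Path] = []

    def stage(name):
        def deco(fn):
            def run(*a, **kw):
                log.info("stage %s", name)
                try:
                    return fn(*a, **kw)
                except Exception as e:
                    raise RuntimeError(f"stage {name!r} failed: {e}") from e
            return run
        return deco

    design = stage("read_design")(read_design)(config.design)
    matrix = stage("read_protein_groups")(read_protein_groups)(
        config.protein_groups, design
    )
    report["stages"]["read"] = {
        "n_proteins": len(matrix.protein_ids),
        "n_samples": len(matrix.sample_ids),
        "n_missing_cells": matrix.n_missing,
    }
    if matrix.n_missing and config.seed is None:
        raise ValueError("config seed is mandatory: input has missing cells")

    m = stage("log_transform")(preprocess.log_transform)(matrix, config.log_base)
    m = stage("center")(preprocess.center_by_sample_mean)(m, config.center_stat)
    m = stage("scale")(preprocess.scale_by_sample_width)(m, config.width_stat)
    m, removed = stage("filter")(preprocess.filter_by_validity)(
        m, config.min_valid_per_group
    )
    report["stages"]["filter"] = {
        "n_removed": len(removed), "n_retained": len(m.values),
    }
    m = stage("impute")(preprocess.impute_min_probabilistic)(
        m, config.down_shift, config.impute_width, config.seed
    )
    report["stages"]["impute"] = {"n_imputed_cells": m.n_imputed}
    report["provenance"] = [dict(s) for s in m.provenance]

    norm_path = out / "normalized.tsv"
    flags_path = out / "imputed_flags.tsv"
    m.values.rename_axis("accession").to_csv(norm_path, sep="\t", float_format="%.10g")
    m.imputed.rename_axis("accession").astype(int).to_csv(flags_path, sep="\t")
    written += [norm_path, flags_path]

    contrasts = config.contrasts or design.isolates
    de_tables = {}
    report["contrasts"] = {}
    for iso in contrasts:
        table, summary = stage(f"de:{iso}")(run_de_table)(
            m, iso, config.alpha_f, config.fc_threshold,
            config.p_threshold, config.strict,
        )
        de_tables[iso] = table
        path = out / f"de_{iso.replace('/', '_').replace('+', 'plus')}.tsv"
        write_de_table(table, path)
        written.append(path)
        report["contrasts"][iso] = {
            "n_tested": summary["n_tested"], "n_up": summary["n_up"],
            "n_down": summary["n_down"],
            "n_excluded": len(summary["excluded"]),
        }
        log.info("DE %s: %d up, %d down of %d tested",
                 iso, summary["n_up"], summary["n_down"], summary["n_tested"])

    if len(de_tables) >= 1:
        sets = stage("set_analysis")(extract_sets)(de_tables)
        up_path, down_path = out / "venn_up.tsv", out / "venn_down.tsv"
        write_region_report(sets.up_regions, up_path)
        write_region_report(sets.down_regions, down_path)
        written += [up_path, down_path]
        report["venn"] = {
            "up": {"&".join(sorted(k)): v for k, v in sets.up_regions.counts.items()},
            "down": {"&".join(sorted(k)): v for k, v in sets.down_regions.counts.items()},
        }

        if config.go_map is not None:
            gomap = stage("read_go_map")(read_go_map)(config.go_map)
            report["go"] = {}
            for iso in contrasts:
                for direction, s in (("up", sets.up_sets[iso]),
                                     ("down", sets.down_sets[iso])):
                    summ = stage(f"go:{iso}:{direction}")(summarize_go)(s, gomap)
                    tag = iso.replace('/', '_').replace('+', 'plus')
                    path = out / f"go_{tag}_{direction}.tsv"
                    write_go_summary(summ, path)
                    written.append(path)
                    report["go"][f"{iso}:{direction}"] = {
                        "n_terms": len(summ),
                        "n_unannotated": len(summ.unannotated),
                    }

    ord_res = stage("ordination")(pca)(m, config.n_components)
    scores_path = out / "pca_scores.tsv"
    load_path = out / "pca_loadings.tsv"
    var_path = out / "pca_variance.tsv"
    ord_res.scores.rename_axis("sample_id").to_csv(scores_path, sep="\t", float_format="%.10g")
    ord_res.loadings.rename_axis("accession").to_csv(load_path, sep="\t", float_format="%.10g")
    pd.DataFrame({
        "component": [f"PC{i+1}" for i in range(len(ord_res.variance_explained))],
        "variance_explained": ord_res.variance_explained,
    }).to_csv(var_path, sep="\t", index=False, float_format="%.10g")
    written += [scores_path, load_path, var_path]
    report["ordination"] = {
        "variance_explained": [float(v) for v in ord_res.variance_explained],
    }

    report["manifest"] = {p.name: _sha256(p) for p in written}
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
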