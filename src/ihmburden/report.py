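"""Full-analysis driver: enrichment tables, charge summary, burden, SRX.

``run_full_analysis`` reproduces the study's summary outputs from a single
configuration: the HCM and DCM regional-enrichment tables, the head-context
breakdown, the charge-change comparison of observed vs expected (from SNV
enumeration over a CDS), the case/control burden table, and the duty-cycle
numbers — written as TSVs plus one machine-readable JSON.  Outputs are
deterministic for a fixed config and seed.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import fixtures
from ._aa import SCALES
from .case_control import burden_table, load_counts_table
from .charge import (charge_change_fraction, delta_q, enumerate_snvs,
                     expected_charge_change)
from .enrichment import (CONTEXT_SELECTORS, DCM_TABLE_SELECTORS,
                         HCM_TABLE_SELECTORS, binom_test, enrichment_table,
                         format_table, results_as_dicts)
from .regions import SELECTORS, parse_regions
from .srx import OrientationFractions, duty_cycle, relative_atp_rate, srx_drx_from_ds
from .synth import gen_cds
from .variants import annotate, load_variant_table, records_from_table

log = logging.getLogger("ihmburden")

_KNOWN_KEYS = {
    "variants_hcm_pv", "variants_hcm_lpv", "variants_dcm", "regions",
    "counts", "charge_scale", "sidedness", "correction", "outdir", "seed",
    "cds_codons", "f_par", "ds_assumed", "fold_inhibition",
}


@dataclass
class AnalysisConfig:
    """Paths and options for a full run; packaged fixtures fill any gaps."""

    variants_hcm_pv: str | None = None
    variants_hcm_lpv: str | None = None
    variants_dcm: str | None = None
    regions: str | None = None
    counts: str | None = None
    charge_scale: str = "paper"
    sidedness: str = "two"
    correction: str = "none"
    outdir: str = "ihm_report"
    seed: int = 0
    cds_codons: int = 1935
    f_par: float = 0.70
    ds_assumed: float = 0.80
    fold_inhibition: float = 5.0
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _stage(name: str):
    log.info("stage: %s", name)


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run every stage and write the report bundle; returns the JSON dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scale = SCALES[config.charge_scale]
    report: dict = {"seed": config.seed, "charge_scale": scale.name}

    try:
        _stage("regions")
        rs = (parse_regions(config.regions) if config.regions
              else fixtures.load_regions())

        _stage("variants")
        def _load(path, default):
            df = load_variant_table(path) if path else default()
            return df
        pv_df = _load(config.variants_hcm_pv, fixtures.load_hcm_pv_table)
        lpv_df = _load(config.variants_hcm_lpv, fixtures.load_hcm_lpv_table)
        dcm_df = _load(config.variants_dcm, fixtures.load_dcm_table)
        hcm = records_from_table(
            pd.concat([pv_df, lpv_df], ignore_index=True).query("gene == 'MYH7'"))
        dcm = records_from_table(dcm_df.query("gene == 'MYH7'"))
        if not hcm:
            raise ValueError("no HCM MYH7 variants parsed")
        log.info("parsed %d HCM and %d DCM MYH7 records", len(hcm), len(dcm))

        _stage("enrichment")
        ann_hcm = annotate(hcm, rs)
        ann_dcm = annotate(dcm, rs)
        t4 = enrichment_table(ann_hcm, rs, HCM_TABLE_SELECTORS, sided=config.sidedness)
        t5 = enrichment_table(ann_dcm, rs, DCM_TABLE_SELECTORS, sided=config.sidedness)
        ctx = enrichment_table(ann_hcm, rs, CONTEXT_SELECTORS, sided=config.sidedness)
        mesa = enrichment_table(ann_hcm, rs, ("mesa",), sided=config.sidedness)
        (outdir / "hcm_enrichment.tsv").write_text(format_table(t4))
        (outdir / "dcm_enrichment.tsv").write_text(format_table(t5))
        (outdir / "hcm_contexts.tsv").write_text(format_table(list(ctx) + list(mesa)))
        report["hcm_enrichment"] = results_as_dicts(t4)
        report["dcm_enrichment"] = results_as_dicts(t5)
        report["hcm_contexts"] = results_as_dicts(list(ctx) + list(mesa))

        _stage("charge")
        sel = SELECTORS["ihm_all"]
        pv_recs = records_from_table(pv_df.query("gene == 'MYH7'"))
        ihm_pv = [a.record for a in annotate(pv_recs, rs) if a.matches(sel)]
        ihm_dcm = [a.record for a in ann_dcm if a.matches(sel)]
        census = enumerate_snvs(gen_cds(config.cds_codons, config.seed), scale)
        expected = expected_charge_change(census)
        k, n, frac = charge_change_fraction(ihm_pv, scale)
        kd, nd, fracd = charge_change_fraction(ihm_dcm, scale)
        report["charge"] = {
            "hcm_pv_changed": k, "hcm_pv_total": n, "hcm_pv_fraction": frac,
            "dcm_changed": kd, "dcm_total": nd, "dcm_fraction": fracd,
            "expected_fraction": expected,
            "hcm_pv_p_value": binom_test(k, n, expected, sided=config.sidedness),
            "census": {
                "n_codons": census.n_codons, "n_events": census.n_events,
                "synonymous": census.n_synonymous, "missense": census.n_missense,
                "nonsense": census.n_nonsense,
                "missense_by_sign": list(census.missense_by_sign),
            },
        }
        lines = ["cohort\tchanged\ttotal\tfraction\texpected"]
        lines.append(f"HCM PV (IHM)\t{k}\t{n}\t{frac:.3f}\t{expected:.3f}")
        lines.append(f"DCM (IHM)\t{kd}\t{nd}\t{fracd:.3f}\t{expected:.3f}")
        (outdir / "charge_summary.tsv").write_text("\n".join(lines) + "\n")

        _stage("burden")
        counts = (load_counts_table(config.counts) if config.counts
                  else fixtures.load_burden_counts())
        (outdir / "burden.tsv").write_text(
            burden_table(counts, correction=config.correction))
        from .case_control import burden as _burden
        report["burden"] = [{
            "site": c.site_label,
            "odds_ratio": _burden(c, config.correction).odds_ratio,
            "etiologic_fraction": _burden(c, config.correction).etiologic_fraction,
            "p_value": _burden(c, config.correction).p_value,
        } for c in counts]

        _stage("srx")
        dc = duty_cycle(OrientationFractions(config.f_par, 1.0 - config.f_par))
        report["srx"] = {
            "skeletal": {
                "f_par": config.f_par, "R": dc.R, "D_s": dc.D_s,
                "srx_drx": dc.srx_drx, "srx_fraction": dc.srx_fraction,
                "relative_atp_rate": relative_atp_rate(
                    dc.srx_fraction, config.fold_inhibition),
            },
            "cardiac_assumed": {
                "D_s": config.ds_assumed,
                "srx_drx": srx_drx_from_ds(config.ds_assumed),
                "srx_fraction": (2.0 - config.ds_assumed) / 2.0,
                "relative_atp_rate": relative_atp_rate(
                    (2.0 - config.ds_assumed) / 2.0, config.fold_inhibition),
            },
        }
    except Exception:
        log.exception("analysis aborted")
        raise

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def setup_logging(logfile: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(level=logging.INFO, handlers=handlers,
                        format="%(levelname)s %(name)s: %(message)s", force=True)
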