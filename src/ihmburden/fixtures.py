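"""Loaders for the packaged cohort and region fixtures.

The variant tables transcribe the published HCM pathogenic (PV), HCM likely
pathogenic (LPV) and DCM cohort tables, including each row's structural
annotations (IHM interaction cells, motor-domain function, mesa membership)
and its printed charge change.  The region fixture is reconstructed from
those annotations by :func:`ihmburden.synth.build_fixture_regions`; the
packaged ``regions.tsv`` is that builder's output, committed for direct
use.

Two transcription caveats (both recorded in the methods note): one PV
substitution carries multiplicity 2 so that event totals match the
published 40 PV / 135 combined counts — the published tables do not say
which substitution is encoded twice, and the fixture's placement (E483K)
is the unique choice consistent with every published aggregate; and the
printed charge change "0" for R453S is transcribed as -2 (the value every
other printed arginine substitution implies).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .case_control import CohortCounts, load_counts_table
from .regions import RegionSet, parse_regions
from .variants import (AnnotatedVariant, VariantRecord, annotate,
                       load_variant_table, records_from_table)


def _data(name: str):
    return resources.files("ihmburden.data").joinpath(name)


def load_table(name: str) -> pd.DataFrame:
    with resources.as_file(_data(name)) as path:
        return load_variant_table(path)


def load_hcm_pv_table() -> pd.DataFrame:
    return load_table("hcm_pv.tsv")


def load_hcm_lpv_table() -> pd.DataFrame:
    return load_table("hcm_lpv.tsv")


def load_dcm_table() -> pd.DataFrame:
    return load_table("dcm.tsv")


def load_regions() -> RegionSet:
    with resources.as_file(_data("regions.tsv")) as path:
        return parse_regions(path)


def load_burden_counts() -> list[CohortCounts]:
    with resources.as_file(_data("burden_counts.tsv")) as path:
        return load_counts_table(path)


def hcm_records(pclasses: tuple[str, ...] = ("PV", "LPV"),
                gene: str | None = "MYH7") -> list[VariantRecord]:
    """HCM cohort records, by default the 135 MYH7 PV+LPV events."""
    frames = []
    if "PV" in pclasses:
        frames.append(load_hcm_pv_table())
    if "LPV" in pclasses:
        frames.append(load_hcm_lpv_table())
    df = pd.concat(frames, ignore_index=True)
    if gene is not None:
        df = df[df.gene == gene]
    return records_from_table(df)


def dcm_records(gene: str | None = "MYH7") -> list[VariantRecord]:
    df = load_dcm_table()
    if gene is not None:
        df = df[df.gene == gene]
    return records_from_table(df)


def annotated_hcm(pclasses: tuple[str, ...] = ("PV", "LPV"),
                  rs: RegionSet | None = None) -> list[AnnotatedVariant]:
    return annotate(hcm_records(pclasses), rs or load_regions())


def annotated_dcm(rs: RegionSet | None = None) -> list[AnnotatedVariant]:
    return annotate(dcm_records(), rs or load_regions())
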