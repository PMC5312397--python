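"""Readers and writers for instrument-style exports and report files.

Two CSV dialects are supported, both documented in the README:

* ``calls_csv`` — long format, one row per sample x assay:
  ``sample_id, assay_id, call[, quality]`` with calls in
  {HOM1, HOM2, HET, NOAMP, UNDET} (vendor call strings such as
  "Homozygous Allele 1" are mapped through a configurable synonym table);
* ``traces_csv`` — long format, one row per cycle:
  ``sample_id, assay_id, cycle, f1, f2``.

Parsers reject structural ambiguity (duplicate sample x assay rows, empty
files) rather than guessing; recoverable oddities (unknown call strings,
missing assay rows) are repaired with a logged warning.  Writers always
produce files the parsers accept.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .authenticate import ContaminationReport, Disposition, Status, ValidationVerdict
from .errors import InputFormatError
from .panel import Category, GenotypeCall, SNPAssay, SNPProfile, Sex, infer_sex
from .signal import SignalTrace

logger = logging.getLogger(__name__)

#: Vendor call-string synonyms accepted on input (case-insensitive).
CALL_SYNONYMS = {
    "HOM1": Category.HOM1,
    "HOM2": Category.HOM2,
    "HET": Category.HET,
    "NOAMP": Category.NOAMP,
    "UNDET": Category.UNDET,
    "HOMOZYGOUS ALLELE 1": Category.HOM1,
    "HOMOZYGOUS ALLELE 2": Category.HOM2,
    "ALLELE 1": Category.HOM1,
    "ALLELE 2": Category.HOM2,
    "HETEROZYGOUS": Category.HET,
    "BOTH ALLELES": Category.HET,
    "NO AMPLIFICATION": Category.NOAMP,
    "NOAMP/UNDETERMINED": Category.UNDET,
    "UNDETERMINED": Category.UNDET,
}


def parse_genotype_export(
    path,
    assays: tuple[SNPAssay, ...],
    synonyms: dict[str, Category] | None = None,
) -> list[SNPProfile]:
    """Parse a calls_csv export into one profile per sample.

    Unknown call strings map to UNDET with a warning; samples missing an
    assay row get NOAMP there, also with a warning.  Duplicate
    (sample, assay) rows and empty files are rejected.
    """
    syn = {k.upper(): v for k, v in (synonyms or CALL_SYNONYMS).items()}
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise InputFormatError(f"{path}: empty file") from None
    required = {"sample_id", "assay_id", "call"}
    if not required.issubset(df.columns):
        raise InputFormatError(
            f"{path}: header must contain {sorted(required)}, got {list(df.columns)}"
        )
    if df.empty:
        raise InputFormatError(f"{path}: no data rows")
    dup = df.duplicated(subset=["sample_id", "assay_id"])
    if dup.any():
        row = df[dup].iloc[0]
        raise InputFormatError(
            f"{path}: duplicate entry for sample {row['sample_id']!r} "
            f"assay {row['assay_id']!r} (row {int(df.index[dup][0]) + 2})"
        )
    assay_ids = [a.assay_id for a in assays]
    y_ids = [a.assay_id for a in assays if a.y_linked]
    profiles = []
    for sample_id, grp in df.groupby("sample_id", sort=False):
        by_assay = dict(zip(grp["assay_id"], grp["call"]))
        calls: dict[str, GenotypeCall] = {}
        for aid in assay_ids:
            if aid not in by_assay:
                logger.warning(
                    "%s: sample %s missing assay %s; recorded as NOAMP",
                    path, sample_id, aid,
                )
                calls[aid] = GenotypeCall(Category.NOAMP)
                continue
            raw = str(by_assay[aid]).strip()
            cat = syn.get(raw.upper())
            if cat is None:
                logger.warning(
                    "%s: unknown call string %r for sample %s assay %s; "
                    "recorded as UNDET", path, raw, sample_id, aid,
                )
                cat = Category.UNDET
            calls[aid] = GenotypeCall(cat)
        prof = SNPProfile(sample_id=str(sample_id), calls=calls)
        prof.inferred_sex = infer_sex(prof, y_ids) if y_ids else Sex.UNKNOWN
        profiles.append(prof)
    return profiles


def write_calls_csv(profiles: list[SNPProfile], path) -> None:
    rows = [
        {"sample_id": p.sample_id, "assay_id": aid, "call": call.category.value,
         "quality": call.quality}
        for p in profiles
        for aid, call in p.calls.items()
    ]
    pd.DataFrame(rows, columns=["sample_id", "assay_id", "call", "quality"]).to_csv(
        path, index=False
    )


def write_traces_csv(traces_by_sample: dict[str, dict[str, SignalTrace]], path) -> None:
    frames = []
    for sample_id, traces in traces_by_sample.items():
        for aid, tr in traces.items():
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": sample_id,
                        "assay_id": aid,
                        "cycle": np.arange(1, tr.cycles + 1),
                        "f1": tr.f1,
                        "f2": tr.f2,
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6g")


def read_traces_csv(path) -> dict[str, dict[str, SignalTrace]]:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise InputFormatError(f"{path}: empty file") from None
    required = {"sample_id", "assay_id", "cycle", "f1", "f2"}
    if not required.issubset(df.columns):
        raise InputFormatError(f"{path}: header must contain {sorted(required)}")
    out: dict[str, dict[str, SignalTrace]] = {}
    for (sample_id, aid), grp in df.groupby(["sample_id", "assay_id"], sort=False):
        grp = grp.sort_values("cycle")
        if grp["cycle"].duplicated().any():
            raise InputFormatError(
                f"{path}: duplicate cycle rows for {sample_id}/{aid}"
            )
        out.setdefault(str(sample_id), {})[str(aid)] = SignalTrace(
            str(aid), grp["f1"].to_numpy(), grp["f2"].to_numpy()
        )
    return out


def write_reports(
    verdicts: list[ValidationVerdict],
    reports: dict[str, ContaminationReport] | None,
    out_dir,
) -> dict[str, Path]:
    """Write the three text reports plus the machine-readable verdict CSV.

    ``summary.txt`` lists every sample with its status; ``contaminated.txt``
    and ``validated.txt`` partition the batch into flagged and validated
    samples (every sample appears in exactly one of the two).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reports = reports or {}
    validated = [v for v in verdicts if v.status is Status.VALIDATED]
    flagged = [v for v in verdicts if v.status is not Status.VALIDATED]

    paths = {
        "summary": out / "summary.txt",
        "contaminated": out / "contaminated.txt",
        "validated": out / "validated.txt",
        "verdicts": out / "verdicts.csv",
    }
    with open(paths["summary"], "w") as fh:
        fh.write("SNP genotyping summary\n")
        fh.write(f"samples: {len(verdicts)}\n")
        fh.write(f"validated: {len(validated)}\n")
        fh.write(f"flagged: {len(flagged)}\n\n")
        for v in verdicts:
            rep = reports.get(v.sample_id)
            extra = f" [{rep.disposition.value}]" if rep is not None else ""
            fh.write(
                f"{v.sample_id}\t{v.status.value}{extra}\t"
                f"expected={v.expected_reference}\tbest={v.best_reference}\t"
                f"concordance={v.comparison.concordance:.3f}\n"
            )
    with open(paths["contaminated"], "w") as fh:
        for v in flagged:
            rep = reports.get(v.sample_id)
            detail = (
                f"\t{rep.disposition.value}\tflagged_loci={rep.n_flagged}"
                + (
                    f"\timplied_contributor={rep.implied_second_contributor}"
                    f"\testimated_fraction={rep.estimated_fraction:.3f}"
                    if rep.implied_second_contributor and rep.estimated_fraction is not None
                    else ""
                )
                if rep is not None
                else ""
            )
            fh.write(f"{v.sample_id}\t{v.status.value}{detail}\n")
    with open(paths["validated"], "w") as fh:
        for v in validated:
            fh.write(f"{v.sample_id}\t{v.best_reference}\n")

    rows = []
    for v in verdicts:
        rep = reports.get(v.sample_id)
        rows.append(
            {
                "sample_id": v.sample_id,
                "expected_reference": v.expected_reference,
                "best_reference": v.best_reference,
                "status": v.status.value,
                "n_informative": v.comparison.n_informative,
                "n_strong_mismatch": v.comparison.n_strong_mismatch,
                "n_weak_mismatch": v.comparison.n_weak_mismatch,
                "n_undetermined": v.comparison.n_undetermined,
                "concordance": v.comparison.concordance,
                "disposition": rep.disposition.value if rep else "",
                "n_flagged_loci": rep.n_flagged if rep else "",
                "implied_second_contributor": (
                    rep.implied_second_contributor or "" if rep else ""
                ),
                "estimated_fraction": (
                    rep.estimated_fraction if rep and rep.estimated_fraction is not None else ""
                ),
                "notes": "; ".join(v.notes),
            }
        )
    pd.DataFrame(rows).to_csv(paths["verdicts"], index=False)
    return paths
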