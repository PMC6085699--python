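"""Readers and writers for the plain-text input formats.

All genomic coordinates are 1-based with inclusive start and end (SEG
convention). Chromosome names are normalised on input by stripping any
``chr`` prefix. Formats:

* probe matrix TSV — columns ``probe_id, chrom, pos`` then one column per
  sample;
* SEG TSV — ``sample_id, chrom, start, end[, n_probes], mean_value[, status]``;
* variant TSV (minimal VCF semantics) — ``sample_id, chrom, pos, ref, alt``;
* fusion TSV (BEDPE-style) — ``sample_id, chrom5, pos5, gene5, chrom3,
  pos3, gene3``;
* clinical CSV — ``patient_id, laterality, interval_days, histology_1,
  er_1, her2_1, subtype_1, histology_2, er_2, her2_2, subtype_2`` with the
  token ``ND`` for missing values;
* manifest CSV — ``patient_id, sample_id, tumour_index`` linking samples to
  patients (tumour_index in {1, 2}).
"""

from __future__ import annotations

import logging

import pandas as pd

from .datatypes import (
    ClinicalRecord,
    FusionSet,
    Platform,
    Probe,
    ProbeProfile,
    Segment,
    SegmentedProfile,
    VariantSet,
    normalise_chrom,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_probe_matrix",
    "write_probe_matrix",
    "read_segments",
    "write_segments",
    "read_variants",
    "write_variants",
    "read_fusions",
    "write_fusions",
    "read_clinical",
    "write_clinical",
    "read_manifest",
    "write_manifest",
]


class ParseError(ValueError):
    pass


def _read_table(path, sep, required):
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file, no header")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df


def read_probe_matrix(path, platform: Platform | str) -> list[ProbeProfile]:
    """Read a probe-level value matrix into one profile per sample column."""
    platform = Platform(platform)
    df = _read_table(path, "\t", ["probe_id", "chrom", "pos"])
    sample_cols = [c for c in df.columns if c not in ("probe_id", "chrom", "pos")]
    if df.empty:
        logger.warning("%s: probe matrix has no data rows", path)
        return []
    try:
        pos = df["pos"].astype(int)
        values = df[sample_cols].astype(float)
    except ValueError as exc:
        # find the first offending row for a useful message
        for i, row in df.iterrows():
            try:
                int(row["pos"])
                [float(row[c]) for c in sample_cols]
            except ValueError:
                raise ParseError(
                    f"{path}: malformed numeric field on line {i + 2}"
                ) from exc
        raise ParseError(f"{path}: {exc}") from exc
    probes = [
        Probe(pid, normalise_chrom(ch), int(p))
        for pid, ch, p in zip(df["probe_id"], df["chrom"], pos)
    ]
    return [
        ProbeProfile(col, platform, list(probes), values[col].to_numpy())
        for col in sample_cols
    ]


def write_probe_matrix(profiles: list[ProbeProfile], path) -> None:
    """Write profiles sharing one probe set as a single matrix TSV."""
    ref = profiles[0]
    data = {
        "probe_id": ref.probe_ids,
        "chrom": [p.chrom for p in ref.probes],
        "pos": [p.pos for p in ref.probes],
    }
    for prof in profiles:
        if prof.probe_ids != ref.probe_ids:
            raise ValueError("profiles must share one probe set to share a matrix")
        data[prof.sample_id] = prof.values
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_segments(path) -> list[SegmentedProfile]:
    """Read a SEG-style TSV (1-based inclusive coordinates).

    A ``status`` column (loss/normal/gain) is honoured when present;
    otherwise status is re-thresholded from ``mean_value`` at +/-0.3.
    """
    df = _read_table(path, "\t", ["sample_id", "chrom", "start", "end", "mean_value"])
    profiles = []
    for sid, grp in df.groupby("sample_id", sort=True):
        segs = []
        for _, row in grp.iterrows():
            mean = float(row["mean_value"])
            if "status" in df.columns and isinstance(row.get("status"), str):
                status = row["status"]
            else:
                status = "gain" if mean > 0.3 else ("loss" if mean < -0.3 else "normal")
            segs.append(
                Segment(
                    normalise_chrom(row["chrom"]),
                    int(row["start"]),
                    int(row["end"]),
                    mean,
                    status,
                )
            )
        profiles.append(SegmentedProfile(str(sid), segs))
    return profiles


def write_segments(profiles: list[SegmentedProfile], path) -> None:
    rows = [
        (p.sample_id, s.chrom, s.start, s.end, s.mean_value, s.status)
        for p in profiles
        for s in p.segments
    ]
    pd.DataFrame(
        rows, columns=["sample_id", "chrom", "start", "end", "mean_value", "status"]
    ).to_csv(path, sep="\t", index=False)


def read_variants(path) -> list[VariantSet]:
    """Read a minimal variant TSV; duplicate keys collapse with a warning."""
    df = _read_table(path, "\t", ["sample_id", "chrom", "pos", "ref", "alt"])
    out = []
    for sid, grp in df.groupby("sample_id", sort=True):
        tuples = [
            (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
            for _, row in grp.iterrows()
        ]
        vs = VariantSet(str(sid), tuples)
        if len(vs) < len(tuples):
            logger.warning(
                "%s: sample %s has %d duplicated variant keys (deduplicated)",
                path, sid, len(tuples) - len(vs),
            )
        out.append(vs)
    return out


def write_variants(variant_sets: list[VariantSet], path) -> None:
    rows = [
        (vs.sample_id, *v) for vs in variant_sets for v in sorted(vs.variants)
    ]
    pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "ref", "alt"]).to_csv(
        path, sep="\t", index=False
    )


def read_fusions(path) -> list[FusionSet]:
    df = _read_table(
        path, "\t",
        ["sample_id", "chrom5", "pos5", "gene5", "chrom3", "pos3", "gene3"],
    )
    return [
        FusionSet(
            str(sid),
            [
                (r["chrom5"], int(r["pos5"]), r["gene5"],
                 r["chrom3"], int(r["pos3"]), r["gene3"])
                for _, r in grp.iterrows()
            ],
        )
        for sid, grp in df.groupby("sample_id", sort=True)
    ]


def write_fusions(fusion_sets: list[FusionSet], path) -> None:
    rows = [
        (fs.sample_id, *f) for fs in fusion_sets for f in sorted(fs.fusions)
    ]
    pd.DataFrame(
        rows,
        columns=["sample_id", "chrom5", "pos5", "gene5", "chrom3", "pos3", "gene3"],
    ).to_csv(path, sep="\t", index=False)


_CLINICAL_COLS = [
    "patient_id", "laterality", "interval_days",
    "histology_1", "er_1", "her2_1", "subtype_1",
    "histology_2", "er_2", "her2_2", "subtype_2",
]


def read_clinical(path) -> list[ClinicalRecord]:
    df = _read_table(path, ",", _CLINICAL_COLS)
    records = []
    for _, row in df.iterrows():
        records.append(
            ClinicalRecord(
                patient_id=str(row["patient_id"]),
                laterality=row["laterality"],
                interval_days=int(row["interval_days"]),
                histology=(row["histology_1"], row["histology_2"]),
                er=(row["er_1"], row["er_2"]),
                her2=(row["her2_1"], row["her2_2"]),
                subtype=(row["subtype_1"], row["subtype_2"]),
            )
        )
    return records


def write_clinical(records: list[ClinicalRecord], path) -> None:
    rows = [
        (
            r.patient_id, r.laterality, r.interval_days,
            r.histology[0], r.er[0], r.her2[0], r.subtype[0],
            r.histology[1], r.er[1], r.her2[1], r.subtype[1],
        )
        for r in records
    ]
    pd.DataFrame(rows, columns=_CLINICAL_COLS).to_csv(path, index=False)


def read_manifest(path) -> dict[str, tuple[str, str]]:
    """Read the patient/sample manifest into patient_id -> (s1, s2)."""
    df = _read_table(path, ",", ["patient_id", "sample_id", "tumour_index"])
    mapping: dict[str, dict[int, str]] = {}
    for _, row in df.iterrows():
        idx = int(row["tumour_index"])
        if idx not in (1, 2):
            raise ParseError(f"{path}: tumour_index must be 1 or 2, got {idx}")
        mapping.setdefault(str(row["patient_id"]), {})[idx] = str(row["sample_id"])
    out = {}
    for pid, d in mapping.items():
        if set(d) != {1, 2}:
            raise ParseError(
                f"{path}: patient {pid} must have exactly tumour indices 1 and 2"
            )
        out[pid] = (d[1], d[2])
    return out


def write_manifest(patient_samples: dict[str, tuple[str, str]], path) -> None:
    rows = [
        (pid, sid, i + 1)
        for pid, samples in sorted(patient_samples.items())
        for i, sid in enumerate(samples)
    ]
    pd.DataFrame(rows, columns=["patient_id", "sample_id", "tumour_index"]).to_csv(
        path, index=False
    )
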