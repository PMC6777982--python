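"""Readers and writers for the tab-separated cohort schema.

A cohort directory contains ``regions.tsv`` (parcellation geometry and
pairing), ``subjects.tsv`` (clinical records), one ``bold_<id>.tsv``
(regions x timepoints) and one ``conn_<id>.tsv`` (N x N integer weights)
per subject, and optionally ``truth.tsv`` with the planted lags. All files
are UTF-8 TSV with a header row; matrices carry row ids in the first column
and serialize infinity as ``inf``. Parse failures raise :class:`SchemaError`
naming the offending file and line.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import CohortConfig, Connectome, SubjectRecord, validate_regions
from .exceptions import SchemaError
from .lag import BoldMatrix
from .synthetic import Cohort

__all__ = [
    "read_matrix",
    "write_matrix",
    "write_cohort",
    "read_cohort",
    "load_config",
]

_FLOAT_FMT = "{:.9g}"


def write_matrix(matrix: np.ndarray, path, row_ids=None, col_ids=None) -> None:
    """Write a matrix as TSV: header of column ids, id-labelled rows.

    Floats are written at 9 significant digits; ``inf`` entries survive a
    round trip.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("matrix must be 2-D")
    n, m = matrix.shape
    row_ids = list(range(n)) if row_ids is None else list(row_ids)
    col_ids = list(range(m)) if col_ids is None else list(col_ids)
    if len(row_ids) != n or len(col_ids) != m:
        raise ValueError("id lengths must match matrix shape")
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("id\t" + "\t".join(str(c) for c in col_ids) + "\n")
        for rid, row in zip(row_ids, matrix):
            cells = ["inf" if math.isinf(v) else _FLOAT_FMT.format(v) for v in row]
            fh.write(str(rid) + "\t" + "\t".join(cells) + "\n")


def read_matrix(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a TSV matrix; returns ``(values, row_ids, col_ids)``.

    Raises :class:`SchemaError` with the line number on ragged rows,
    non-numeric cells or duplicate row ids.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise SchemaError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise SchemaError(f"{path}: line 1: header must contain an id column and columns")
    col_ids = header[1:]
    rows, row_ids = [], []
    seen = set()
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise SchemaError(
                f"{path}: line {lineno}: expected {len(header)} fields, got {len(cells)}"
            )
        rid = cells[0]
        if rid in seen:
            raise SchemaError(f"{path}: line {lineno}: duplicate row id {rid!r}")
        seen.add(rid)
        row_ids.append(rid)
        try:
            rows.append([float(c) for c in cells[1:]])
        except ValueError as exc:
            raise SchemaError(f"{path}: line {lineno}: non-numeric cell ({exc})") from None
    return np.asarray(rows, dtype=float), row_ids, col_ids


def _subjects_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "age_years": s.age_years,
                "age_range": s.age_range or "",
                "gender": s.gender or "",
                "lesion_side": s.lesion_side or "",
                "lesion_radius_mm": s.lesion_radius_mm,
                "lesion_locations": ";".join(s.lesion_locations),
                "lesion_regions": ";".join(str(r) for r in sorted(s.lesion_regions)),
                "lesion_centroids": ";".join(
                    ",".join(_FLOAT_FMT.format(v) for v in c) for c in s.lesion_centroids
                ),
                "stroke_type": s.stroke_type or "",
                "onset_years": s.onset_years,
                "arat": s.arat,
            }
        )
    return pd.DataFrame(rows)


def _subjects_from_frame(frame: pd.DataFrame) -> list[SubjectRecord]:
    """Rebuild records from an all-string frame (empty cell = missing)."""

    def _str(v):
        return "" if v is None or pd.isna(v) else str(v).strip()

    def _float(v):
        s = _str(v)
        return float(s) if s else None

    out = []
    for _, r in frame.iterrows():
        centroids = [
            tuple(float(x) for x in c.split(","))
            for c in _str(r.get("lesion_centroids")).split(";")
            if c
        ]
        arat = _float(r.get("arat"))
        radius = _float(r.get("lesion_radius_mm"))
        out.append(
            SubjectRecord(
                subject_id=_str(r["subject_id"]),
                group=_str(r["group"]),
                lesion_centroids=centroids,
                lesion_regions={
                    int(float(v))
                    for v in _str(r.get("lesion_regions")).split(";")
                    if v
                },
                lesion_side=_str(r.get("lesion_side")) or None,
                lesion_radius_mm=radius if radius is not None else 0.0,
                lesion_locations=[v for v in _str(r.get("lesion_locations")).split(";") if v],
                stroke_type=_str(r.get("stroke_type")) or None,
                onset_years=_float(r.get("onset_years")),
                age_years=_float(r.get("age_years")),
                age_range=_str(r.get("age_range")) or None,
                gender=_str(r.get("gender")) or None,
                arat=None if arat is None else int(arat),
            )
        )
    return out


def write_cohort(cohort: Cohort, outdir) -> Path:
    """Write a cohort directory (regions, subjects, bold/conn matrices, truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.regions.reset_index(drop=True).to_csv(outdir / "regions.tsv", sep="\t", index=False)
    _subjects_frame(cohort.subjects).to_csv(outdir / "subjects.tsv", sep="\t", index=False)
    truth_rows = []
    for rec in cohort.subjects:
        bold = cohort.bold[rec.subject_id]
        write_matrix(
            bold.values,
            outdir / f"bold_{rec.subject_id}.tsv",
            row_ids=bold.region_ids,
            col_ids=[f"t{k}" for k in range(bold.n_timepoints)],
        )
        if rec.subject_id in cohort.connectomes:
            conn = cohort.connectomes[rec.subject_id]
            write_matrix(
                conn.weights,
                outdir / f"conn_{rec.subject_id}.tsv",
                row_ids=conn.region_ids,
                col_ids=conn.region_ids,
            )
        for pair_id, tau in sorted(rec.planted_lags.items()):
            truth_rows.append((rec.subject_id, pair_id, tau))
    if truth_rows:
        pd.DataFrame(
            truth_rows, columns=["subject_id", "pair_id", "planted_lag_seconds"]
        ).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    if cohort.config is not None:
        meta = {"tr_seconds": cohort.config.tr_seconds, "seed": cohort.config.seed}
        (outdir / "cohort.yaml").write_text(yaml.safe_dump(meta), encoding="utf-8")
    return outdir


def read_cohort(indir, tr_seconds: float | None = None) -> Cohort:
    """Read a cohort directory written by :func:`write_cohort`.

    ``tr_seconds`` overrides the TR recorded in ``cohort.yaml`` (required if
    that file is absent).
    """
    indir = Path(indir)
    regions_path = indir / "regions.tsv"
    subjects_path = indir / "subjects.tsv"
    for p in (regions_path, subjects_path):
        if not p.exists():
            raise SchemaError(f"missing cohort file: {p}")
    regions = validate_regions(pd.read_csv(regions_path, sep="\t"))
    subjects = _subjects_from_frame(
        pd.read_csv(subjects_path, sep="\t", dtype=str, keep_default_na=False)
    )
    if tr_seconds is None:
        meta_path = indir / "cohort.yaml"
        if not meta_path.exists():
            raise SchemaError(f"no TR given and {meta_path} is missing")
        tr_seconds = float(yaml.safe_load(meta_path.read_text(encoding="utf-8"))["tr_seconds"])
    bold = {}
    connectomes = {}
    region_ids = regions["region_id"].to_numpy()
    coords = regions[["x", "y", "z"]].to_numpy(dtype=float)
    for rec in subjects:
        bpath = indir / f"bold_{rec.subject_id}.tsv"
        if not bpath.exists():
            raise SchemaError(f"missing BOLD file: {bpath}")
        values, row_ids, _ = read_matrix(bpath)
        if [str(r) for r in row_ids] != [str(r) for r in region_ids]:
            raise SchemaError(f"{bpath}: row ids do not match regions.tsv")
        bold[rec.subject_id] = BoldMatrix(values, tr_seconds, region_ids)
        cpath = indir / f"conn_{rec.subject_id}.tsv"
        if cpath.exists():
            w, row_ids, _ = read_matrix(cpath)
            if [str(r) for r in row_ids] != [str(r) for r in region_ids]:
                raise SchemaError(f"{cpath}: row ids do not match regions.tsv")
            connectomes[rec.subject_id] = Connectome(w, coords, region_ids)
    truth_path = indir / "truth.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t")
        for rec in subjects:
            sub = truth[truth["subject_id"] == rec.subject_id]
            rec.planted_lags = dict(
                zip(sub["pair_id"].astype(int), sub["planted_lag_seconds"].astype(float))
            )
    return Cohort(regions, subjects, bold, connectomes)


def load_config(path) -> CohortConfig:
    """Build a :class:`CohortConfig` from a flat YAML/JSON key-value file."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: config must be a flat key-value mapping")
    known = set(CohortConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"{path}: unknown config keys: {sorted(unknown)}")
    if "band_hz" in raw:
        raw["band_hz"] = tuple(raw["band_hz"])
    return CohortConfig(**raw)
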