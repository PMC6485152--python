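"""Delimited-text readers and writers for the package's file formats.

Formats (all UTF-8 text):

* patient table — CSV with header ``patient_id,age,hlos,codes``; the codes
  field is a semicolon-joined list of taxonomy code strings.
* strata spec — YAML list of ``{label, age_min, age_max, hlos_min, hlos_max}``.
* prototype table — CSV ``label,rank,code,score``.
* distance matrix — CSV, first row/column are code labels, full symmetric.
* results table — tidy CSV ``triple,k,tp,fp,fn,tn,precision,recall,fscore``.

Floats are written with 12 significant digits everywhere so that identical
runs produce byte-identical files.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DomainError
from .evaluation import EvaluationResult
from .prototype import PatientRecord, Prototype, SubpopulationSpec
from .taxonomy import Taxonomy

__all__ = [
    "FLOAT_FMT",
    "read_patient_table",
    "write_patient_table",
    "read_strata",
    "write_prototypes",
    "read_prototypes",
    "write_distance_matrix",
    "read_distance_matrix",
    "write_results",
]

FLOAT_FMT = "%.12g"


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


def read_patient_table(path, taxonomy: Taxonomy | None = None) -> list[PatientRecord]:
    """Load patients from CSV; optionally validate codes against a taxonomy."""
    df = pd.read_csv(path, dtype={"patient_id": str, "codes": str})
    required = {"patient_id", "age", "hlos", "codes"}
    if missing := required - set(df.columns):
        raise DomainError(f"{path}: missing columns {sorted(missing)}")
    patients = []
    for row in df.itertuples(index=False):
        codes = frozenset(c.strip() for c in str(row.codes).split(";") if c.strip())
        if taxonomy is not None:
            if unknown := sorted(c for c in codes if c not in taxonomy):
                raise DomainError(
                    f"{path}: patient {row.patient_id!r} has codes not in the "
                    f"taxonomy: {unknown}"
                )
        patients.append(PatientRecord(str(row.patient_id), int(row.age), int(row.hlos), codes))
    return patients


def write_patient_table(patients: Iterable[PatientRecord], path) -> None:
    df = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "age": [p.age for p in patients],
            "hlos": [p.hlos for p in patients],
            "codes": [";".join(sorted(p.codes)) for p in patients],
        }
    )
    df.to_csv(path, index=False)


def read_strata(path) -> list[SubpopulationSpec]:
    """Load subpopulation specs from a YAML list."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list) or not raw:
        raise ConfigurationError(f"{path}: expected a non-empty YAML list of strata")
    try:
        return [
            SubpopulationSpec(
                label=str(item["label"]),
                age_min=int(item["age_min"]), age_max=int(item["age_max"]),
                hlos_min=int(item["hlos_min"]), hlos_max=int(item["hlos_max"]),
            )
            for item in raw
        ]
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"{path}: malformed stratum entry ({exc})") from exc


def write_prototypes(protos: Mapping[str, Prototype], path) -> None:
    rows = [
        (label, rank, code, _fmt(score))
        for label, proto in sorted(protos.items())
        for rank, (code, score) in enumerate(proto.ranked_codes, 1)
    ]
    pd.DataFrame(rows, columns=["label", "rank", "code", "score"]).to_csv(path, index=False)


def read_prototypes(path, strata: Sequence[SubpopulationSpec] = ()) -> dict[str, Prototype]:
    df = pd.read_csv(path, dtype={"label": str, "code": str})
    by_label = {s.label: s for s in strata}
    protos = {}
    for label, grp in df.groupby("label", sort=True):
        grp = grp.sort_values("rank")
        ranked = tuple((str(r.code), float(r.score)) for r in grp.itertuples(index=False))
        protos[str(label)] = Prototype(str(label), ranked, by_label.get(str(label)))
    return protos


def write_distance_matrix(codes: Sequence[str], matrix: np.ndarray, path) -> None:
    df = pd.DataFrame(np.asarray(matrix), index=list(codes), columns=list(codes))
    df.to_csv(path, float_format=FLOAT_FMT)


def read_distance_matrix(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, index_col=0)
    return [str(c) for c in df.columns], df.to_numpy(dtype=float)


def write_results(results: Iterable[EvaluationResult], path) -> None:
    rows = [
        (r.triple_name, r.k, r.tp, r.fp, r.fn, r.tn,
         _fmt(r.precision), _fmt(r.recall), _fmt(r.fscore))
        for r in results
    ]
    pd.DataFrame(
        rows,
        columns=["triple", "k", "tp", "fp", "fn", "tn", "precision", "recall", "fscore"],
    ).to_csv(path, index=False)
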