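"""Readers and writers for the flat-file interfaces.

All tabular interchange is tab-separated text:

- profiles:  ``admission_id<TAB>term_id`` long format (one row per annotation)
- diagnoses: ``admission_id<TAB>code``
- corpus:    ``entity_id<TAB>term_id``
- IC table:  ``term_id<TAB>method<TAB>ic``
- roster:    an INI-style key-value file listing measure ids per category

Headers are optional on input and always written on output.  The synthetic
ontology writer emits a minimal OBO 1.2 file that round-trips through
:func:`phenosim.ontology.read_obo`.
"""

from __future__ import annotations

import configparser
from pathlib import Path
from typing import IO, Mapping, Sequence

import pandas as pd

from .benchmark import LabeledAdmission
from .ic import AnnotationCorpus, ICTable
from .ontology import OntologyGraph
from .similarity import MeasureDescriptor, PhenotypeProfile, default_roster

__all__ = [
    "read_pairs_tsv",
    "read_profiles_tsv",
    "read_diagnoses_tsv",
    "read_corpus_tsv",
    "load_admissions",
    "read_roster",
    "write_profiles_tsv",
    "write_diagnoses_tsv",
    "write_corpus_tsv",
    "write_ic_table_tsv",
    "write_registry_tsv",
    "write_obo",
]

_HEADER_TOKENS = {"admission_id", "entity_id", "term_id", "code", "diagnosis"}


def read_pairs_tsv(path: str | Path | IO[str]) -> pd.DataFrame:
    """Two-column TSV with an optional header row."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"expected 2 tab-separated columns, got {df.shape[1]}")
    if str(df.iloc[0, 0]).lower() in _HEADER_TOKENS:
        df = df.iloc[1:].reset_index(drop=True)
    if df.isna().any().any():
        raise ValueError("missing fields in TSV input")
    df.columns = ["key", "value"]
    return df


def read_profiles_tsv(path: str | Path | IO[str]) -> dict[str, frozenset[str]]:
    """Admission -> term-set map from long-format annotation rows."""
    df = read_pairs_tsv(path)
    return {
        adm: frozenset(group["value"])
        for adm, group in df.groupby("key", sort=True)
    }


def read_diagnoses_tsv(path: str | Path | IO[str]) -> dict[str, str]:
    """Admission -> primary diagnosis code map; duplicate admissions error."""
    df = read_pairs_tsv(path)
    if df["key"].duplicated().any():
        dups = df["key"][df["key"].duplicated()].tolist()
        raise ValueError(f"duplicate admission ids in diagnoses: {dups[:5]}")
    return dict(zip(df["key"], df["value"]))


def read_corpus_tsv(path: str | Path | IO[str]) -> AnnotationCorpus:
    return AnnotationCorpus(read_profiles_tsv(path))


def load_admissions(
    profiles: Mapping[str, frozenset[str]], diagnoses: Mapping[str, str]
) -> list[LabeledAdmission]:
    """Join profile and diagnosis tables into labelled admissions (id order)."""
    missing = sorted(set(profiles) - set(diagnoses))
    if missing:
        raise ValueError(f"admissions lacking a diagnosis: {missing[:5]}")
    return [
        LabeledAdmission(aid, PhenotypeProfile(aid, frozenset(profiles[aid])), diagnoses[aid])
        for aid in sorted(profiles)
    ]


def read_roster(path: str | Path | IO[str]) -> list[MeasureDescriptor]:
    """Measure roster from an INI-style file.

    Expected layout::

        [measures]
        groupwise = gic avg max
        pairwise  = rada resnik
        ic        = resnik seco

    Ids must exist in the package registry; listing an id under the wrong
    category is an error.
    """
    parser = configparser.ConfigParser()
    if hasattr(path, "read"):
        parser.read_string(path.read())
    else:
        text = Path(path).read_text()
        parser.read_string(text)
    if "measures" not in parser:
        raise ValueError("roster file needs a [measures] section")
    section = parser["measures"]
    known = {(m.level.split("-")[0] if m.level.startswith("groupwise") else m.level, m.id): m
             for m in default_roster()}
    by_category: dict[str, list[str]] = {
        cat: section.get(cat, "").replace(",", " ").split()
        for cat in ("groupwise", "pairwise", "ic")
    }
    roster: list[MeasureDescriptor] = []
    for cat, ids in by_category.items():
        for mid in ids:
            m = known.get((cat, mid))
            if m is None:
                valid = sorted(i for c, i in known if c == cat)
                raise ValueError(f"unknown {cat} measure {mid!r}; valid: {valid}")
            roster.append(m)
    if not roster:
        raise ValueError("empty measure roster")
    return roster


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _open(path: str | Path | IO[str], write: bool = True):
    if hasattr(path, "write"):
        return path, False
    return open(path, "w"), True


def _write_pairs(path, rows, header: tuple[str, str]) -> None:
    handle, close = _open(path)
    try:
        handle.write(f"{header[0]}\t{header[1]}\n")
        for a, b in rows:
            handle.write(f"{a}\t{b}\n")
    finally:
        if close:
            handle.close()


def write_profiles_tsv(path, admissions: Sequence[LabeledAdmission]) -> None:
    rows = [
        (a.admission_id, t)
        for a in admissions
        for t in sorted(a.profile.terms)
    ]
    _write_pairs(path, rows, ("admission_id", "term_id"))


def write_diagnoses_tsv(path, admissions: Sequence[LabeledAdmission]) -> None:
    rows = [(a.admission_id, a.diagnosis) for a in admissions]
    _write_pairs(path, rows, ("admission_id", "code"))


def write_corpus_tsv(path, corpus: AnnotationCorpus) -> None:
    rows = [
        (e, t)
        for e in sorted(corpus.annotations)
        for t in sorted(corpus.annotations[e])
    ]
    _write_pairs(path, rows, ("entity_id", "term_id"))


def write_ic_table_tsv(path, table: ICTable) -> None:
    handle, close = _open(path)
    try:
        handle.write("term_id\tmethod\tic\n")
        for t in sorted(table.values):
            handle.write(f"{t}\t{table.method}\t{table.values[t]:.10g}\n")
    finally:
        if close:
            handle.close()


def write_registry_tsv(path, roster: Sequence[MeasureDescriptor] | None = None) -> None:
    roster = list(default_roster() if roster is None else roster)
    handle, close = _open(path)
    try:
        handle.write("id\tlevel\tneeds_ic\tneeds_pairwise\n")
        for m in roster:
            handle.write(f"{m.id}\t{m.level}\t{int(m.needs_ic)}\t{int(m.needs_pairwise)}\n")
    finally:
        if close:
            handle.close()


def write_obo(path, g: OntologyGraph, ontology_name: str = "synthetic") -> None:
    """Minimal OBO 1.2 serialisation of the is_a taxonomy."""
    handle, close = _open(path)
    try:
        handle.write("format-version: 1.2\n")
        handle.write(f"ontology: {ontology_name}\n")
        for t in sorted(g.terms):
            handle.write(f"\n[Term]\nid: {t}\n")
            for p in sorted(g.parents[t]):
                handle.write(f"is_a: {p}\n")
    finally:
        if close:
            handle.close()
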