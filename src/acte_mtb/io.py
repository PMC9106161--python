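"""Readers, writers, the packaged validation fixture, and report bundles.

The response interchange format is a wide UTF-8 CSV: one row per respondent,
a ``respondent_id`` column plus one column per survey question id;
multi-select cells join option codes with ";". The same dialect is written
by the simulator and read by the scorer, so cohorts round-trip losslessly.

The packaged fixture carries the published per-MTB validation scores of the
20-board study cohort (overall + four domain scores, institution type,
country, therapy implementation rate). The fixture stores *scores*, not raw
answers — the raw per-question responses were never published — so
fixture-based commands start at the assessment layer while raw-answer
commands use simulated cohorts.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import io
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .errors import CohortError
from .rubric import DOMAINS, Rubric
from .scoring import MaturityAssessment, ResponseRecord, score_cohort
from .stats import (
    ACADEMIC,
    NON_ACADEMIC,
    DEFAULT_STRATIFICATION,
    StratificationRule,
    cohort_summary,
    round_half_up,
    stratify,
    students_t_test,
)

log = logging.getLogger("acte_mtb")

MULTISELECT_DELIM = ";"

#: sha256 of the packaged per-MTB score table; load_table4_fixture verifies it
_FIXTURE_SHA256 = "9aa4367b25565a8e877f8399d0e97705bab81e53b5eed2489948c0cd1a13ebda"

#: fixture institution labels -> canonical institution-type codes
_FIXTURE_INSTITUTIONS = {
    "Academic": "academic_medical_center",
    "Community": "community_hospital",
    "Specialized center": "specialized_cancer_clinic",
    "Private": "private_practice",
}


# --------------------------------------------------------------- responses IO
def write_responses(records: Sequence[ResponseRecord], path: str | Path, rubric: Rubric) -> None:
    """Write a cohort as the wide-CSV dialect (header = question ids)."""
    qids = [q.id for q in rubric.schema.questions]
    rows = []
    for rec in records:
        row = {"respondent_id": rec.respondent_id}
        for qid in qids:
            a = rec.answers.get(qid)
            if a is None:
                row[qid] = ""
            elif isinstance(a, str):
                row[qid] = a
            else:
                row[qid] = MULTISELECT_DELIM.join(a)
        rows.append(row)
    pd.DataFrame(rows, columns=["respondent_id"] + qids).to_csv(
        path, index=False, encoding="utf-8"
    )


def read_responses(path: str | Path, rubric: Rubric) -> list[ResponseRecord]:
    """Read a wide CSV/TSV of survey responses into validated records.

    Unknown columns are rejected (listing the unmatched headers); rows whose
    gating answer is "no" — respondents who do not participate in a board —
    are excluded with a logged reason, mirroring the survey's exit mechanism.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, dtype=str, sep=sep, keep_default_na=False)

    known = {q.id for q in rubric.schema.questions}
    unknown = [c for c in df.columns if c != "respondent_id" and c not in known]
    if unknown:
        raise CohortError(f"{path.name}: unknown columns: {', '.join(sorted(unknown))}")
    gate = rubric.schema.gating_question_id
    for required in (gate, "institution_type"):
        if required not in df.columns:
            raise CohortError(f"{path.name}: missing required column {required!r}")

    records: list[ResponseRecord] = []
    n_excluded = 0
    for i, row in df.iterrows():
        rid = row.get("respondent_id") or f"row-{i + 1}"
        if str(row[gate]).strip().lower() == "no":
            n_excluded += 1
            log.info("excluding %s: gating question %r answered 'no'", rid, gate)
            continue
        answers: dict = {}
        for qid in df.columns:
            if qid == "respondent_id":
                continue
            cell = str(row[qid]).strip()
            q = rubric.question(qid)
            if cell == "":
                answers[qid] = None
            elif q.response_mode == "multi-select":
                codes = [c.strip() for c in cell.split(MULTISELECT_DELIM) if c.strip()]
                if not codes:
                    raise CohortError(f"{path.name} row {i + 2}: malformed multi-select cell")
                answers[qid] = codes
            else:
                answers[qid] = cell
        roles = answers.get("respondent_roles") or ()
        records.append(
            ResponseRecord(
                respondent_id=str(rid),
                answers=answers,
                country=answers.get("country"),
                institution_type=answers.get("institution_type"),
                roles=tuple(roles),
            )
        )
    if n_excluded:
        log.info("excluded %d respondent(s) via the gating question", n_excluded)
    return records


# ------------------------------------------------------------------- fixture
@dataclass(frozen=True)
class Table4Row:
    institution_type: str  # canonical code
    institution_label: str  # as printed
    country: str
    overall: float
    consultation: float
    evidence: float
    technology: float
    access: float
    implementation_rate_pct: float
    imputed_not_sure: bool

    def domain_scores(self) -> dict[str, float]:
        return {
            "Access": self.access,
            "Consultation": self.consultation,
            "Technology": self.technology,
            "Evidence": self.evidence,
        }


@dataclass(frozen=True)
class Table4Fixture:
    rows: tuple[Table4Row, ...]
    notes: tuple[str, ...]
    sha256: str

    @property
    def n_academic(self) -> int:
        return sum(r.institution_type == "academic_medical_center" for r in self.rows)

    @property
    def n_non_academic(self) -> int:
        return len(self.rows) - self.n_academic


#: print inconsistencies in the published score table, carried as metadata
_FIXTURE_NOTES = (
    "South Korea academic row: printed overall 3.0 differs from 3.1, the "
    "rounded mean of its printed domain scores (overall was computed from "
    "unrounded domain scores).",
    "Third Germany community row: printed overall 3.9 is inconsistent with "
    "its printed domain mean 3.65 beyond rounding; kept as printed.",
    "Four rows carry implementation rates imputed at 25% for an "
    "\"I'm not sure\" answer (flag column imputed_not_sure).",
)


def load_table4_fixture() -> Table4Fixture:
    """The packaged 20-board validation score table, checksum-pinned."""
    res = importlib.resources.files("acte_mtb.data") / "table4.csv"
    raw = res.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise CohortError(
            f"fixture checksum mismatch: {digest} != {_FIXTURE_SHA256}"
        )
    df = pd.read_csv(io.BytesIO(raw))
    rows = tuple(
        Table4Row(
            institution_type=_FIXTURE_INSTITUTIONS[r.institution_type],
            institution_label=r.institution_type,
            country=r.country,
            overall=float(r.overall),
            consultation=float(r.consultation),
            evidence=float(r.evidence),
            technology=float(r.technology),
            access=float(r.access),
            implementation_rate_pct=float(r.implementation_rate_pct),
            imputed_not_sure=bool(r.imputed_not_sure),
        )
        for r in df.itertuples(index=False)
    )
    return Table4Fixture(rows=rows, notes=_FIXTURE_NOTES, sha256=digest)


# -------------------------------------------------------------------- report
def _comparison_payload(groups: dict[str, list], metric) -> dict:
    payload = {}
    for label in (ACADEMIC, NON_ACADEMIC):
        values = [metric(item) for item in groups.get(label, [])]
        s = cohort_summary(values, label)
        payload[label] = {
            "n": s.n,
            "mean": s.mean,
            "mean_rounded": round_half_up(s.mean),
            "se": s.se,
            "se_rounded": round_half_up(s.se) if s.se is not None else None,
        }
    all_values = [metric(item) for items in groups.values() for item in items]
    s = cohort_summary(all_values, "all")
    payload["all"] = {
        "n": s.n,
        "mean": s.mean,
        "mean_rounded": round_half_up(s.mean),
        "se": s.se,
        "se_rounded": round_half_up(s.se) if s.se is not None else None,
    }
    test = students_t_test(
        [metric(i) for i in groups.get(ACADEMIC, [])],
        [metric(i) for i in groups.get(NON_ACADEMIC, [])],
        labels=(ACADEMIC, NON_ACADEMIC),
    )
    payload["t_test"] = {"t": test.t, "df": test.df, "p": test.p}
    return payload


def compare_report(
    items: Sequence,
    metrics: dict[str, object],
    rule: StratificationRule = DEFAULT_STRATIFICATION,
) -> dict:
    """Stratified comparison (academic vs. non-academic vs. all) per metric."""
    groups = stratify(items, rule)
    return {name: _comparison_payload(groups, metric) for name, metric in metrics.items()}


def fixture_comparison(fixture: Table4Fixture) -> dict:
    """The headline validation statistics recomputed from the fixture."""
    metrics = {
        "overall": lambda r: r.overall,
        "consultation": lambda r: r.consultation,
        "evidence": lambda r: r.evidence,
        "technology": lambda r: r.technology,
        "access": lambda r: r.access,
        "implementation_rate_pct": lambda r: r.implementation_rate_pct,
    }
    return compare_report(list(fixture.rows), metrics)


def run_report(
    source,
    rubric: Rubric,
    outdir: str | Path,
    *,
    charts: bool = False,
    seed: Optional[int] = None,
) -> dict:
    """End-to-end report bundle: scores CSV/JSON + comparison JSON (+ charts).

    ``source`` is either a list of :class:`ResponseRecord` (scored through
    the engine) or a :class:`Table4Fixture` (already at the assessment
    layer). Every artifact embeds the rubric and software versions (and the
    seed when the cohort was simulated), making reports self-describing.
    Deterministic: identical inputs produce identical bundles.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"rubric_version": rubric.version, "software_version": __version__}
    if seed is not None:
        meta["seed"] = seed

    if isinstance(source, Table4Fixture):
        rows = [
            {
                "institution_type": r.institution_type,
                "country": r.country,
                "overall": r.overall,
                **{d.lower(): r.domain_scores()[d] for d in DOMAINS},
                "implementation_rate_pct": r.implementation_rate_pct,
                "imputed_not_sure": r.imputed_not_sure,
            }
            for r in source.rows
        ]
        comparison = fixture_comparison(source)
        scores_payload = {"meta": meta, "fixture_notes": list(source.notes), "rows": rows}
        assessments: list[MaturityAssessment] = []
    else:
        records: list[ResponseRecord] = list(source)
        if not records:
            raise CohortError("no respondents")
        assessments = score_cohort(records, rubric)
        rows = []
        for a in assessments:
            row = {
                "respondent_id": a.respondent_id,
                "institution_type": a.institution_type,
                "country": a.country,
                "overall": a.overall,
            }
            for d in DOMAINS:
                row[d.lower()] = a.domain_scores[d].score
                row[f"{d.lower()}_level"] = a.domain_scores[d].level
            rows.append(row)
        comparison = compare_report(
            assessments, {"overall": lambda x: x.overall,
                          **{d.lower(): (lambda x, d=d: x.domain_scores[d].score)
                             for d in DOMAINS}}
        )
        scores_payload = {"meta": meta, "rows": rows}

    # CSV applies the reporting rounding rule (half-up, 1 dp); JSON keeps
    # full precision
    df = pd.DataFrame(rows)
    for col in df.columns:
        if df[col].dtype.kind == "f":
            df[col] = df[col].map(lambda x: round_half_up(x))
    scores_csv = outdir / "scores.csv"
    df.to_csv(scores_csv, index=False, encoding="utf-8")

    scores_json = outdir / "scores.json"
    scores_json.write_text(json.dumps(scores_payload, indent=2, sort_keys=True) + "\n")
    comparison_json = outdir / "comparison.json"
    comparison_json.write_text(
        json.dumps({"meta": meta, "comparison": comparison}, indent=2, sort_keys=True) + "\n"
    )

    chart_paths = []
    if charts and assessments:
        from .viz import render_radial_chart

        ranked = sorted(assessments, key=lambda a: (a.overall, a.respondent_id))
        pair = [ranked[-1]] if len(ranked) == 1 else [ranked[-1], ranked[0]]
        chart = outdir / "radial_extremes.svg"
        render_radial_chart(pair, rubric, path=chart)
        chart_paths.append(str(chart))

    return {
        "meta": meta,
        "scores_csv": str(scores_csv),
        "scores_json": str(scores_json),
        "comparison_json": str(comparison_json),
        "charts": chart_paths,
        "comparison": comparison,
    }
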