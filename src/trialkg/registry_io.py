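"""Reading the legacy ClinicalTrials.gov XML dialect and flattening results.

The registry's "AllPublicXML" layout stores one document per study, named by
the NCT id. A document carries the study design (``<arm_group>`` elements
with experimental/comparator types), per-outcome statistical-analysis blocks
(``<analysis>`` under ``<outcome>``; group titles are indirected through
``group_id`` references), and reported adverse events (``<event>`` elements
grouped by body-system category, with per-arm affected/at-risk counts).

Parsing is lossless for the fields in scope: every analysis block and every
event count element maps to exactly one :class:`~trialkg.records.StatAnalysis`
/ :class:`~trialkg.records.ReportedEvent`. Absent sections yield empty lists,
never failure.
"""

from __future__ import annotations

import csv
import json
import logging
import zipfile
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

from lxml import etree

from trialkg.records import (
    DesignArm,
    OutcomeMeasure,
    ReportedEvent,
    StatAnalysis,
    TrialRecord,
    arm_role_from_type,
    normalize_ws,
)

logger = logging.getLogger(__name__)

XmlSource = Union[str, Path, bytes]


class RegistryParseError(ValueError):
    """Malformed or unusable registry XML; carries the source path if known."""

    def __init__(self, message: str, source: Optional[str] = None) -> None:
        self.source = source
        super().__init__(f"{message}" + (f" [{source}]" if source else ""))


def _text(parent: etree._Element, tag: str) -> Optional[str]:
    el = parent.find(tag)
    if el is None or el.text is None:
        return None
    t = normalize_ws(el.text)
    return t or None


def _float(parent: etree._Element, tag: str) -> Optional[float]:
    t = _text(parent, tag)
    if t is None:
        return None
    try:
        return float(t.replace(",", ""))
    except ValueError:
        return None


def _rank_from_type(type_str: Optional[str]) -> str:
    if not type_str:
        return "other"
    t = type_str.strip().lower()
    if t == "primary":
        return "primary"
    if t == "secondary":
        return "secondary"
    return "other"


def _group_title_map(parent: etree._Element) -> dict[str, str]:
    """Map group_id -> group title for an outcome or reported_events block."""
    titles: dict[str, str] = {}
    gl = parent.find("group_list")
    if gl is None:
        return titles
    for group in gl.findall("group"):
        gid = group.get("group_id")
        title = _text(group, "title")
        if gid and title:
            titles[gid] = title
    return titles


def _parse_analysis(el: etree._Element, group_titles: dict[str, str]) -> Optional[StatAnalysis]:
    ids = [g.text.strip() for g in el.findall("group_id_list/group_id") if g.text and g.text.strip()]
    titles = [group_titles.get(i, i) for i in ids]
    if not titles:
        return None
    non_inf = _text(el, "non_inferiority_type")
    return StatAnalysis(
        group_titles=titles,
        p_value_raw=_text(el, "p_value"),
        method=_text(el, "method"),
        param_name_raw=_text(el, "param_type"),
        param_value=_float(el, "param_value"),
        ci_percent=_float(el, "ci_percent"),
        ci_lower_raw=_text(el, "ci_lower_limit"),
        ci_upper_raw=_text(el, "ci_upper_limit"),
        non_inferiority=(non_inf.lower() != "superiority") if non_inf else None,
    )


def _parse_outcomes(results: etree._Element) -> list[OutcomeMeasure]:
    outcomes: list[OutcomeMeasure] = []
    for outcome_el in results.findall("outcome_list/outcome"):
        title = _text(outcome_el, "title")
        if title is None:
            continue
        rank = _rank_from_type(_text(outcome_el, "type"))
        group_titles = _group_title_map(outcome_el)
        analyses = []
        for an_el in outcome_el.findall("analysis_list/analysis"):
            an = _parse_analysis(an_el, group_titles)
            if an is not None:
                analyses.append(an)
        outcomes.append(OutcomeMeasure(title=title, rank=rank, analyses=analyses))
    return outcomes


def _count_value(counts_el: etree._Element, attr: str) -> Optional[int]:
    # counts appear either as attributes on <counts> or as child elements —
    # both registry dialects are accepted
    v = counts_el.get(attr)
    if v is None:
        child = counts_el.find(attr)
        v = child.text if child is not None else None
    if v is None:
        return None
    try:
        return int(str(v).strip())
    except ValueError:
        return None


def _parse_events(results: etree._Element) -> list[ReportedEvent]:
    ev_root = results.find("reported_events")
    if ev_root is None:
        return []
    group_titles = _group_title_map(ev_root)
    events: list[ReportedEvent] = []
    for severity, section in (("serious", "serious_events"), ("other", "other_events")):
        sec = ev_root.find(section)
        if sec is None:
            continue
        for cat_el in sec.findall("category_list/category"):
            category = _text(cat_el, "title") or "Uncategorized"
            for event_el in cat_el.findall("event_list/event"):
                sub_title = _text(event_el, "sub_title")
                if sub_title is None:
                    continue
                for counts_el in event_el.findall("counts"):
                    affected = _count_value(counts_el, "subjects_affected")
                    if affected is None:
                        continue
                    gid = counts_el.get("group_id") or ""
                    events.append(
                        ReportedEvent(
                            arm_title=group_titles.get(gid, gid or "Unknown arm"),
                            event_title=sub_title,
                            category=category,
                            severity=severity,
                            affected=affected,
                            at_risk=_count_value(counts_el, "subjects_at_risk"),
                        )
                    )
    return events


def read_trial_xml(source: XmlSource) -> TrialRecord:
    """Parse one registry XML document into a :class:`TrialRecord`.

    ``source`` is a filesystem path or raw XML bytes. Sections absent from
    the document (no results posted, no adverse events) yield empty lists.

    Raises
    ------
    RegistryParseError
        If the XML is malformed or the document has no ``nct_id``.
    """
    path: Optional[str] = None
    try:
        if isinstance(source, bytes):
            root = etree.fromstring(source, parser=etree.XMLParser(recover=False, encoding=None))
        else:
            path = str(source)
            root = etree.parse(path).getroot()
    except (etree.XMLSyntaxError, OSError) as exc:
        raise RegistryParseError(f"malformed XML: {exc}", source=path) from exc

    nct_id = _text(root, "id_info/nct_id")
    if nct_id is None:
        raise RegistryParseError("document has no id_info/nct_id element", source=path)

    conditions = [normalize_ws(c.text) for c in root.findall("condition") if c.text and c.text.strip()]
    intervention_types = [
        normalize_ws(t.text)
        for t in root.findall("intervention/intervention_type")
        if t.text and t.text.strip()
    ]

    arms: list[DesignArm] = []
    for arm_el in root.findall("arm_group"):
        title = _text(arm_el, "arm_group_label")
        if title is None:
            continue
        arms.append(
            DesignArm(
                title=title,
                role=arm_role_from_type(_text(arm_el, "arm_group_type")),
                description=_text(arm_el, "description"),
            )
        )

    results = root.find("clinical_results")
    outcomes = _parse_outcomes(results) if results is not None else []
    events = _parse_events(results) if results is not None else []

    try:
        return TrialRecord(
            nct_id=nct_id,
            conditions=conditions,
            intervention_types=intervention_types,
            design_arms=arms,
            outcomes=outcomes,
            events=events,
        )
    except ValueError as exc:
        raise RegistryParseError(str(exc), source=path) from exc


class CorpusScan(Iterator[TrialRecord]):
    """Iterator over a corpus directory or zip of registry XML files.

    Yields one record per ``*.xml`` member in lexicographic member order
    (independent of filesystem enumeration order). Unreadable members are
    logged and skipped; their names accumulate in :attr:`skipped`.
    """

    def __init__(self, root: Union[str, Path]) -> None:
        self.root = Path(root)
        self.skipped: list[str] = []
        if not self.root.exists():
            raise FileNotFoundError(f"corpus root does not exist: {self.root}")
        if self.root.is_file() and self.root.suffix == ".zip":
            zf = zipfile.ZipFile(self.root)
            names = sorted(n for n in zf.namelist() if n.lower().endswith(".xml"))
            self._items: list[tuple[str, object]] = [(n, zf) for n in names]
        else:
            names_p = sorted(self.root.glob("*.xml"), key=lambda p: p.name)
            self._items = [(p.name, p) for p in names_p]
        if not self._items:
            logger.warning("corpus at %s contains no *.xml members", self.root)
        self._pos = 0

    def __iter__(self) -> "CorpusScan":
        return self

    def __next__(self) -> TrialRecord:
        while self._pos < len(self._items):
            name, src = self._items[self._pos]
            self._pos += 1
            try:
                if isinstance(src, zipfile.ZipFile):
                    return read_trial_xml(src.read(name))
                return read_trial_xml(src)
            except (RegistryParseError, zipfile.BadZipFile, OSError) as exc:
                logger.warning("skipping unreadable corpus member %s: %s", name, exc)
                self.skipped.append(name)
        logger.info("corpus scan finished, %d member(s) skipped", len(self.skipped))
        raise StopIteration


def scan_corpus(root: Union[str, Path]) -> CorpusScan:
    """Stream :class:`TrialRecord` objects from a directory or zip archive."""
    return CorpusScan(root)


@dataclass
class EfficacyRow:
    """One raw group-outcome comparison row, prior to classification.

    Rows whose analysis does not compare exactly two groups carry
    ``excluded=True`` and are dropped by downstream stages.
    """

    nct_id: str
    group_titles: list[str]
    outcome_title: str
    outcome_rank: str
    p_value_raw: Optional[str]
    method: Optional[str]
    param_name_raw: Optional[str]
    param_value: Optional[float]
    ci_percent: Optional[float]
    ci_lower_raw: Optional[str]
    ci_upper_raw: Optional[str]
    non_inferiority: Optional[bool]
    conditions: list[str]
    intervention_types: list[str]
    excluded: bool = False


#: Frozen column order for efficacy tables, mirroring the registry export
#: (NCT id, groups, outcome, p-value) plus the statistics carried alongside.
EFFICACY_COLUMNS = [
    "nct_id",
    "group_titles",
    "outcome_title",
    "outcome_rank",
    "p_value_raw",
    "method",
    "param_name_raw",
    "param_value",
    "ci_percent",
    "ci_lower_raw",
    "ci_upper_raw",
    "non_inferiority",
    "conditions",
    "intervention_types",
    "excluded",
]


def to_efficacy_rows(trial: TrialRecord) -> list[EfficacyRow]:
    """Flatten a trial into one row per statistical-analysis block.

    Every analysis block becomes a row; blocks comparing a number of groups
    other than two are flagged ``excluded`` (only two-arm comparisons can be
    separated into intervention vs comparator downstream).
    """
    rows: list[EfficacyRow] = []
    for outcome in trial.outcomes:
        for an in outcome.analyses:
            rows.append(
                EfficacyRow(
                    nct_id=trial.nct_id,
                    group_titles=list(an.group_titles),
                    outcome_title=outcome.title,
                    outcome_rank=outcome.rank,
                    p_value_raw=an.p_value_raw,
                    method=an.method,
                    param_name_raw=an.param_name_raw,
                    param_value=an.param_value,
                    ci_percent=an.ci_percent,
                    ci_lower_raw=an.ci_lower_raw,
                    ci_upper_raw=an.ci_upper_raw,
                    non_inferiority=an.non_inferiority,
                    conditions=list(trial.conditions),
                    intervention_types=list(trial.intervention_types),
                    excluded=len(an.group_titles) != 2,
                )
            )
    return rows


def _row_to_dict(row: object) -> dict:
    if isinstance(row, dict):
        return dict(row)
    return asdict(row)  # type: ignore[arg-type]


def _encode_cell(value: object) -> str:
    if value is None:
        return ""
    if isinstance(value, (list, tuple, dict, bool)):
        return json.dumps(value, ensure_ascii=False)
    return str(value)


def _decode_cell(value: str) -> object:
    if value == "":
        return None
    if value and value[0] in "[{" or value in ("true", "false"):
        try:
            return json.loads(value)
        except json.JSONDecodeError:
            return value
    try:
        f = float(value)
    except ValueError:
        return value
    return int(value) if f.is_integer() and "." not in value and "e" not in value.lower() else f


def write_records(
    rows: Iterable[object],
    path: Union[str, Path],
    format: str = "csv",
    columns: Optional[list[str]] = None,
) -> Path:
    """Write a homogeneous record set to CSV or JSONL.

    The round trip is stable: :func:`read_records` reproduces the rows
    field-for-field, and a write→read→write cycle is byte-identical. Column
    order is ``columns`` if given, else the field order of the first row.
    """
    path = Path(path)
    dict_rows = [_row_to_dict(r) for r in rows]
    if columns is None:
        columns = list(dict_rows[0].keys()) if dict_rows else []
    if format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for r in dict_rows:
                fh.write(json.dumps({c: r.get(c) for c in columns}, ensure_ascii=False) + "\n")
    elif format == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(columns)
            for r in dict_rows:
                writer.writerow([_encode_cell(r.get(c)) for c in columns])
    else:
        raise ValueError(f"unknown format {format!r} (expected csv or jsonl)")
    return path


def read_records(path: Union[str, Path], format: str = "csv") -> list[dict]:
    """Read back a table written by :func:`write_records`."""
    path = Path(path)
    if format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            return [json.loads(line) for line in fh if line.strip()]
    if format == "csv":
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh)
            try:
                header = next(reader)
            except StopIteration:
                return []
            return [{c: _decode_cell(v) for c, v in zip(header, row)} for row in reader]
    raise ValueError(f"unknown format {format!r} (expected csv or jsonl)")
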