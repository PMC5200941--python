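"""Registry record parsing.

Reads per-trial XML records in the 2016-era public clinicaltrials.gov
full-study-record dialect (``clinical_study`` root, ``id_info/nct_id``,
``study_type``, ``overall_status``, ``phase``, ``completion_date``,
``primary_completion_date``, ``lead_sponsor/agency`` and ``agency_class``,
``enrollment``, and the two results flags ``firstreceived_results_date`` /
``firstreceived_results_disposition_date``). A serializer for the same
dialect supports round-trip testing and the synthetic corpus generator.
"""
from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

from lxml import etree

from .dates import DateParseError, PartialDate, parse_partial_date

__all__ = [
    "TrialRecord",
    "RecordError",
    "SPONSOR_CLASSES",
    "normalize_sponsor_class",
    "parse_trial_xml",
    "serialize_trial_xml",
    "load_registry",
    "write_parse_log",
]

log = logging.getLogger(__name__)

NCT_ID_PATTERN = re.compile(r"^NCT\d{8}$")

#: The registry's four coarse funder categories.
SPONSOR_CLASSES = ("industry", "NIH", "US Fed", "other")

# Raw agency_class text -> canonical class label. Anything unlisted maps to
# "other" with a warning.
_AGENCY_CLASS_MAP = {
    "industry": "industry",
    "nih": "NIH",
    "u.s. fed": "US Fed",
    "us fed": "US Fed",
    "other": "other",
}


class RecordError(ValueError):
    """A registry record is structurally unusable (bad or missing nct_id)."""


@dataclass(frozen=True)
class TrialRecord:
    """One registry entry, as used by the audit."""

    nct_id: str
    study_type: str | None = None
    overall_status: str | None = None
    phase: str | None = None
    completion_date: PartialDate | None = None
    primary_completion_date: PartialDate | None = None
    lead_sponsor_name: str = ""
    sponsor_class: str = "other"
    enrollment: int | None = None
    has_registry_results: bool = False
    has_results_disposition: bool = False

    def __post_init__(self) -> None:
        if not NCT_ID_PATTERN.match(self.nct_id):
            raise RecordError(f"invalid registry identifier: {self.nct_id!r}")
        if self.sponsor_class not in SPONSOR_CLASSES:
            raise ValueError(f"invalid sponsor class: {self.sponsor_class!r}")
        if self.enrollment is not None and self.enrollment < 0:
            raise ValueError("enrollment must be non-negative")


def normalize_sponsor_class(raw: str | None, *, context: str = "") -> str:
    """Map raw registry ``agency_class`` text onto the four class labels.

    Unknown values map to ``"other"`` with a warning naming the record.
    """
    if raw is None or not raw.strip():
        return "other"
    mapped = _AGENCY_CLASS_MAP.get(raw.strip().lower())
    if mapped is None:
        log.warning("unknown agency class %r%s; mapped to 'other'",
                    raw, f" in {context}" if context else "")
        return "other"
    return mapped


def _text(root: etree._Element, path: str) -> str | None:
    el = root.find(path)
    if el is None or el.text is None or not el.text.strip():
        return None
    return el.text.strip()


def _date(root: etree._Element, path: str, nct_id: str) -> PartialDate | None:
    raw = _text(root, path)
    if raw is None:
        return None
    try:
        return parse_partial_date(raw)
    except DateParseError as exc:
        raise DateParseError(f"{path} of {nct_id}: {exc}") from exc


def parse_trial_xml(document: Union[str, bytes, Path, etree._Element]) -> TrialRecord:
    """Parse one registry XML record into a :class:`TrialRecord`.

    ``document`` may be a path, raw XML text/bytes, or a parsed element.
    Boolean results flags are true iff the corresponding tag is present and
    non-empty. Raises :class:`RecordError` for a missing/invalid identifier
    and :class:`lxml.etree.XMLSyntaxError` for malformed XML.
    """
    if isinstance(document, etree._Element):
        root = document
    elif isinstance(document, Path):
        root = etree.parse(str(document)).getroot()
    elif isinstance(document, bytes):
        root = etree.fromstring(document)
    elif isinstance(document, str) and document.lstrip().startswith("<"):
        root = etree.fromstring(document.encode())
    else:
        root = etree.parse(str(document)).getroot()

    nct_id = _text(root, "id_info/nct_id") or _text(root, "nct_id")
    if nct_id is None or not NCT_ID_PATTERN.match(nct_id):
        raise RecordError(f"missing or invalid nct_id ({nct_id!r})")

    enrollment_raw = _text(root, "enrollment")
    enrollment: int | None = None
    if enrollment_raw is not None:
        try:
            enrollment = int(enrollment_raw)
        except ValueError:
            log.warning("non-numeric enrollment %r in %s; treated as missing",
                        enrollment_raw, nct_id)
    if enrollment is not None and enrollment < 0:
        log.warning("negative enrollment %d in %s; treated as missing", enrollment, nct_id)
        enrollment = None

    return TrialRecord(
        nct_id=nct_id,
        study_type=_text(root, "study_type"),
        overall_status=_text(root, "overall_status"),
        phase=_text(root, "phase"),
        completion_date=_date(root, "completion_date", nct_id),
        primary_completion_date=_date(root, "primary_completion_date", nct_id),
        lead_sponsor_name=_text(root, "lead_sponsor/agency") or "",
        sponsor_class=normalize_sponsor_class(
            _text(root, "lead_sponsor/agency_class"), context=nct_id),
        enrollment=enrollment,
        has_registry_results=_text(root, "firstreceived_results_date") is not None,
        has_results_disposition=_text(root, "firstreceived_results_disposition_date") is not None,
    )


# Canonical agency_class text emitted per class label (inverse of the map).
_CLASS_TO_AGENCY = {"industry": "Industry", "NIH": "NIH", "US Fed": "U.S. Fed", "other": "Other"}


def serialize_trial_xml(trial: TrialRecord) -> bytes:
    """Render a :class:`TrialRecord` back into the registry XML dialect.

    Re-parsing the output yields an identical record. The boolean results
    flags carry no date of their own, so a fixed placeholder date text is
    emitted when a flag is set.
    """
    root = etree.Element("clinical_study")
    id_info = etree.SubElement(root, "id_info")
    etree.SubElement(id_info, "nct_id").text = trial.nct_id

    def add(tag: str, value: str | None) -> None:
        if value is not None:
            etree.SubElement(root, tag).text = value

    sponsor = etree.SubElement(root, "lead_sponsor")
    etree.SubElement(sponsor, "agency").text = trial.lead_sponsor_name
    etree.SubElement(sponsor, "agency_class").text = _CLASS_TO_AGENCY[trial.sponsor_class]

    add("study_type", trial.study_type)
    add("overall_status", trial.overall_status)
    add("phase", trial.phase)
    if trial.completion_date is not None:
        add("completion_date", trial.completion_date.registry_format())
    if trial.primary_completion_date is not None:
        add("primary_completion_date", trial.primary_completion_date.registry_format())
    if trial.enrollment is not None:
        add("enrollment", str(trial.enrollment))
    if trial.has_registry_results:
        add("firstreceived_results_date", "January 1, 2015")
    if trial.has_results_disposition:
        add("firstreceived_results_disposition_date", "January 1, 2015")
    return etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")


def load_registry(directory: Union[str, Path]) -> tuple[list[TrialRecord], list[dict]]:
    """Load every ``*.xml`` record under ``directory``.

    Returns ``(records, parse_log)``. Files are visited in lexicographic
    filename order; for duplicate ``nct_id`` values the first file wins and
    later ones are logged. Unparseable files are logged, never fatal.
    Raises :class:`FileNotFoundError` for a missing directory and
    :class:`ValueError` if the directory holds no XML files.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"registry directory not found: {directory}")
    files = sorted(directory.glob("*.xml"))
    if not files:
        raise ValueError(f"no XML record files in {directory}")

    records: list[TrialRecord] = []
    seen: dict[str, str] = {}
    parse_log: list[dict] = []
    for path in files:
        try:
            record = parse_trial_xml(path)
        except (RecordError, DateParseError) as exc:
            parse_log.append({"file": path.name, "event": "rejected", "reason": str(exc)})
            continue
        except etree.XMLSyntaxError as exc:
            parse_log.append({"file": path.name, "event": "malformed_xml", "reason": str(exc)})
            continue
        if record.nct_id in seen:
            parse_log.append({
                "file": path.name,
                "event": "duplicate_nct_id",
                "reason": f"{record.nct_id} already loaded from {seen[record.nct_id]}",
            })
            continue
        seen[record.nct_id] = path.name
        records.append(record)
    return records, parse_log


def write_parse_log(entries: Iterable[dict], path: Union[str, Path]) -> None:
    """Write parse-log entries as JSON lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for entry in entries:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")
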