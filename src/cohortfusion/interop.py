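"""ACPA result-message service contract: build, validate, parse, notify.

The clinical decision support system obtains ACPA results through a
request/response contract: a ``GetACPAresultRequest`` naming one or more
coded patients is answered with a ``GetACPAresultResponse`` document that
validates against the packaged XSD and carries, per patient measurement,
exactly the four ACPA parameters (CCP serum and the Cit-C1/Cit-Eno/Cit-Fib
IgG serum titres). Missing titres are encoded as explicit xsi:nil elements,
never omitted. An in-process relay emulates the exchange index that pushes
update notifications to registered consumers; the network transport itself
(SOAP, certificates) is out of scope — the contract is the deliverable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass
from decimal import Decimal
from pathlib import Path
from typing import Callable

import pandas as pd
from lxml import etree

from .errors import MessageError
from .store import FusedStore, packaged_data_path

logger = logging.getLogger(__name__)

NS = "urn:cohortfusion:acpa:1"
XSI = "http://www.w3.org/2001/XMLSchema-instance"
SCHEMA_VERSION = "1.0"

_PARAM_TAGS = {
    "ccp_serum": "CcpSerum",
    "cit_c1_igg": "CitC1IgGSerum",
    "cit_eno_igg": "CitEnoIgGSerum",
    "cit_fib_igg": "CitFibIgGSerum",
}

#: Swedish personal-number shape; requests carrying one are rejected outright
_RAW_IDENTIFIER_RE = re.compile(r"^\d{6,8}[-+]\d{4}$")


@dataclass(frozen=True)
class AcpaResultMessage:
    """One ACPA result for one patient measurement (four titres, nullable)."""

    coded_id: str
    result_date: pd.Timestamp
    ccp_serum: float | None
    cit_c1_igg: float | None
    cit_eno_igg: float | None
    cit_fib_igg: float | None
    message_id: str
    schema_version: str = SCHEMA_VERSION


def _schema() -> etree.XMLSchema:
    return etree.XMLSchema(etree.parse(str(packaged_data_path("acpa_result.xsd"))))


def load_contract() -> dict:
    """The packaged service-contract descriptor (operations, pairing, schema)."""
    return json.loads(packaged_data_path("contract.json").read_text())


def message_id_for(coded_id: str, result_date) -> str:
    """Deterministic message identifier: same result ⇒ same id (idempotence)."""
    digest = hashlib.sha1(f"{coded_id}|{pd.Timestamp(result_date).date()}"
                          .encode()).hexdigest()[:12]
    return f"MSG-{digest}"


def _format_titre(v: float) -> str:
    # exact decimal expansion of the float, exponent-free (xs:decimal)
    return format(Decimal(repr(float(v))), "f")


def build_acpa_response(
    store: FusedStore,
    patient_ids: list[str] | None = None,
    updated_since=None,
    schema_version: str = SCHEMA_VERSION,
) -> etree._ElementTree:
    """Assemble and schema-validate a GetACPAresultResponse document.

    ``patient_ids`` selects patients by coded identifier (a raw identifier
    shape in the request is rejected before any lookup); ``updated_since``
    instead selects every serum measurement on or after the given date.
    Unknown coded ids simply contribute no result elements — the empty
    document is still valid.
    """
    sero = store.serology
    sero = sero[sero["source"] == "serum"] if "source" in sero.columns else sero
    if patient_ids is not None:
        for pid in patient_ids:
            if _RAW_IDENTIFIER_RE.fullmatch(str(pid)):
                raise MessageError(
                    f"request contains a raw identifier shape: {pid!r}; "
                    "only coded identifiers may cross the service boundary")
        sero = sero[sero["coded_id"].astype(str).isin({str(p) for p in patient_ids})]
    if updated_since is not None:
        sero = sero[sero["measurement_date"] >= pd.Timestamp(updated_since)]

    sero = sero.sort_values(["coded_id", "measurement_date"], kind="mergesort")
    root = etree.Element(f"{{{NS}}}GetACPAresultResponse",
                         nsmap={None: NS, "xsi": XSI})
    root.set("schemaVersion", schema_version)
    for row in sero.itertuples(index=False):
        res = etree.SubElement(root, f"{{{NS}}}Result")
        res.set("messageId", message_id_for(row.coded_id, row.measurement_date))
        pid = etree.SubElement(res, f"{{{NS}}}PatientId")
        pid.text = str(row.coded_id)
        rdate = etree.SubElement(res, f"{{{NS}}}ResultDate")
        rdate.text = str(pd.Timestamp(row.measurement_date).date())
        for field_, tag in _PARAM_TAGS.items():
            el = etree.SubElement(res, f"{{{NS}}}{tag}")
            value = getattr(row, field_)
            if value is None or pd.isna(value):
                el.set(f"{{{XSI}}}nil", "true")
            else:
                el.text = _format_titre(value)

    tree = etree.ElementTree(root)
    schema = _schema()
    if not schema.validate(tree):
        err = schema.error_log.last_error
        raise MessageError(f"built document violates the contract schema at "
                           f"{err.path}: {err.message}", detail=str(schema.error_log))
    return tree


def messages_to_response(messages: list[AcpaResultMessage],
                         schema_version: str = SCHEMA_VERSION) -> etree._ElementTree:
    """Build a response document directly from message objects."""
    root = etree.Element(f"{{{NS}}}GetACPAresultResponse", nsmap={None: NS, "xsi": XSI})
    root.set("schemaVersion", schema_version)
    for m in messages:
        res = etree.SubElement(root, f"{{{NS}}}Result")
        res.set("messageId", m.message_id)
        etree.SubElement(res, f"{{{NS}}}PatientId").text = m.coded_id
        etree.SubElement(res, f"{{{NS}}}ResultDate").text = str(
            pd.Timestamp(m.result_date).date())
        for field_, tag in _PARAM_TAGS.items():
            el = etree.SubElement(res, f"{{{NS}}}{tag}")
            v = getattr(m, field_)
            if v is None or pd.isna(v):
                el.set(f"{{{XSI}}}nil", "true")
            else:
                el.text = _format_titre(v)
    tree = etree.ElementTree(root)
    schema = _schema()
    if not schema.validate(tree):
        err = schema.error_log.last_error
        raise MessageError(f"document violates the contract schema at "
                           f"{err.path}: {err.message}", detail=str(schema.error_log))
    return tree


def parse_acpa_response(doc) -> list[AcpaResultMessage]:
    """Schema-validate and parse a response document into messages.

    ``doc`` may be an element tree, XML bytes or a file path. Invalid
    documents (malformed XML, missing specificities, schema violations) are
    rejected before any field extraction; the error names the first failure.
    """
    if isinstance(doc, (str, Path)) and Path(str(doc)).exists():
        try:
            tree = etree.parse(str(doc))
        except etree.XMLSyntaxError as exc:
            raise MessageError(f"malformed XML: {exc}") from exc
    elif isinstance(doc, (bytes, str)):
        try:
            tree = etree.ElementTree(etree.fromstring(
                doc.encode() if isinstance(doc, str) else doc))
        except etree.XMLSyntaxError as exc:
            raise MessageError(f"malformed XML: {exc}") from exc
    else:
        tree = doc

    schema = _schema()
    if not schema.validate(tree):
        err = schema.error_log.last_error
        raise MessageError(f"schema validation failed at {err.path}: {err.message}",
                           detail=str(schema.error_log))

    root = tree.getroot()
    version = root.get("schemaVersion")
    out = []
    for res in root.findall(f"{{{NS}}}Result"):
        def _num(tag):
            el = res.find(f"{{{NS}}}{tag}")
            if el is None or el.get(f"{{{XSI}}}nil") == "true":
                return None
            return float(el.text)
        out.append(AcpaResultMessage(
            coded_id=res.findtext(f"{{{NS}}}PatientId"),
            result_date=pd.Timestamp(res.findtext(f"{{{NS}}}ResultDate")),
            ccp_serum=_num("CcpSerum"),
            cit_c1_igg=_num("CitC1IgGSerum"),
            cit_eno_igg=_num("CitEnoIgGSerum"),
            cit_fib_igg=_num("CitFibIgGSerum"),
            message_id=res.get("messageId"),
            schema_version=version,
        ))
    return out


@dataclass(frozen=True)
class DeliveryRecord:
    message_id: str
    coded_id: str
    consumer: str
    queued: bool = False


class NotificationRelay:
    """In-process stand-in for the exchange index of the deployment topology.

    Consumers register a name and a callback; each *new* result (keyed by
    message id — duplicate submissions are idempotent) produces exactly one
    notification per registered consumer. With no consumers the notification
    is queued with a warning and flushed on the next registration. The event
    log allows deterministic replay into freshly registered consumers.
    """

    def __init__(self):
        self.consumers: dict[str, Callable[[dict], None]] = {}
        self.seen: set[str] = set()
        self.event_log: list[dict] = []
        self.pending: list[dict] = []
        self.deliveries: list[DeliveryRecord] = []

    def register(self, name: str, callback: Callable[[dict], None]) -> None:
        self.consumers[name] = callback
        if self.pending:
            for event in list(self.pending):
                self._deliver(event)
            self.pending.clear()

    def _deliver(self, event: dict) -> list[DeliveryRecord]:
        records = []
        for name, cb in self.consumers.items():
            cb(dict(event))
            rec = DeliveryRecord(event["message_id"], event["coded_id"], name)
            records.append(rec)
            self.deliveries.append(rec)
        return records

    def notify_update(self, coded_id: str, result_date) -> list[DeliveryRecord]:
        """Announce a new ACPA result; returns the delivery records."""
        mid = message_id_for(coded_id, result_date)
        if mid in self.seen:
            return []
        self.seen.add(mid)
        event = {"message_id": mid, "coded_id": str(coded_id),
                 "result_date": str(pd.Timestamp(result_date).date())}
        self.event_log.append(event)
        if not self.consumers:
            logger.warning("no registered consumers; queueing notification %s", mid)
            self.pending.append(event)
            return [DeliveryRecord(mid, str(coded_id), "<queued>", queued=True)]
        return self._deliver(event)

    def replay(self, into: "NotificationRelay | None" = None) -> "NotificationRelay":
        """Re-deliver the recorded event log (recovery / idempotence check)."""
        target = into or self
        for event in self.event_log:
            if target.consumers:
                target._deliver(event)
            else:
                target.pending.append(event)
        return target
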