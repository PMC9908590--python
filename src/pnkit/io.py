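"""On-disk interchange formats.

Annotation documents are versioned JSON, terminology tables are TSV, behavior
traces are JSON Lines with a leading header record, region geometry is
GeoJSON (RFC 7946) and patch manifests are CSV.  All writers are
deterministic — fixed key order, fixed float formatting, UTF-8, ``\\n`` line
endings — so repeated saves of equal objects are byte-identical and diffs
stay stable across audit rounds.

Coordinates are level-0 pixels serialized as integers; non-integral floats
are rejected on import because annotation pixels are discrete.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .behavior import EVENT_TYPES, Event, Trace
from .errors import (
    EmptyTerminologyError,
    EventTypeError,
    GeometryError,
    ParseError,
    StructureError,
    TimeOrderError,
    VersionError,
)
from .schema import Bundle, Caption, Region, TermEntry, TerminologyTree, WSIAnnotation

SCHEMA_VERSION = "1.0"
KNOWN_VERSIONS = {"1.0"}

MANIFEST_COLUMNS = [
    "wsi_id", "i", "j", "x0", "y0",
    "label_class", "label_subtype", "tissue_frac", "split", "seed",
]


def _as_pixel(value, where: str) -> int:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ParseError(f"coordinate {value!r} in {where} is not a number", key=where)
    if isinstance(value, float):
        raise ParseError(
            f"coordinate {value!r} in {where} is a float; level-0 pixels are integers",
            key=where,
        )
    return int(value)


def _require(mapping: dict, key: str, where: str):
    if key not in mapping:
        raise ParseError(f"missing key {key!r} in {where}", key=key)
    return mapping[key]


# ---------------------------------------------------------------------------
# annotation documents (JSON)
# ---------------------------------------------------------------------------

def _caption_to_dict(c: Caption) -> dict:
    return {"terms": list(c.terms), "diagnosis_phrase": c.diagnosis_phrase}


def _caption_from_dict(d: dict, where: str) -> Caption:
    return Caption(
        terms=[str(t) for t in _require(d, "terms", where)],
        diagnosis_phrase=d.get("diagnosis_phrase"),
    )


def _region_to_dict(r: Region) -> dict:
    return {
        "id": r.id,
        "wsi_id": r.wsi_id,
        "polygon": [[int(x), int(y)] for x, y in r.polygon],
        "pencil_shape": r.pencil_shape,
        "layer": r.layer,
        "class_label": r.class_label,
        "subtype_label": r.subtype_label,
        "reason_labels": list(r.reason_labels),
        "free_text": r.free_text,
        "voice_ref": r.voice_ref,
        "created_ms": int(r.created_ms),
    }


def _region_from_dict(d: dict) -> Region:
    rid = str(_require(d, "id", "region"))
    where = f"region {rid!r}"
    poly = []
    for pt in _require(d, "polygon", where):
        if not isinstance(pt, (list, tuple)) or len(pt) != 2:
            raise ParseError(f"bad vertex {pt!r} in {where}", key="polygon")
        poly.append((_as_pixel(pt[0], where), _as_pixel(pt[1], where)))
    return Region(
        id=rid,
        wsi_id=str(_require(d, "wsi_id", where)),
        polygon=poly,
        pencil_shape=d.get("pencil_shape", "curve"),
        layer=str(_require(d, "layer", where)),
        class_label=str(_require(d, "class_label", where)),
        subtype_label=d.get("subtype_label"),
        reason_labels=[str(t) for t in d.get("reason_labels", [])],
        free_text=d.get("free_text"),
        voice_ref=d.get("voice_ref"),
        created_ms=int(d.get("created_ms", 0)),
    )


def annotation_to_dict(doc: WSIAnnotation) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "wsi_id": doc.wsi_id,
        "annotator_id": doc.annotator_id,
        "phase": doc.phase,
        "slide_caption": doc.slide_caption,
        "audit_status": doc.audit_status,
        "events_ref": doc.events_ref,
        "regions": [_region_to_dict(r) for r in doc.regions],
        "bundles": [
            {
                "id": b.id,
                "member_region_ids": list(b.member_region_ids),
                "caption": _caption_to_dict(b.caption),
            }
            for b in doc.bundles
        ],
    }


def annotation_from_dict(d: dict) -> WSIAnnotation:
    version = _require(d, "schema_version", "document")
    if version not in KNOWN_VERSIONS:
        raise VersionError(f"unknown schema_version {version!r}", version=version)
    doc = WSIAnnotation(
        wsi_id=str(_require(d, "wsi_id", "document")),
        annotator_id=str(_require(d, "annotator_id", "document")),
        phase=str(_require(d, "phase", "document")),
        slide_caption=d.get("slide_caption"),
        audit_status=d.get("audit_status", "draft"),
        events_ref=d.get("events_ref"),
        regions=[_region_from_dict(r) for r in _require(d, "regions", "document")],
        bundles=[],
    )
    for bd in d.get("bundles", []):
        bid = str(_require(bd, "id", "bundle"))
        doc.bundles.append(
            Bundle(
                id=bid,
                member_region_ids=[str(m) for m in _require(bd, "member_region_ids", f"bundle {bid!r}")],
                caption=_caption_from_dict(_require(bd, "caption", f"bundle {bid!r}"), f"bundle {bid!r}"),
            )
        )
    return doc


def save_annotation(doc: WSIAnnotation, path) -> Path:
    path = Path(path)
    text = json.dumps(annotation_to_dict(doc), indent=2, ensure_ascii=False)
    path.write_text(text + "\n", encoding="utf-8")
    return path


def load_annotation(path) -> WSIAnnotation:
    path = Path(path)
    try:
        d = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise ParseError(f"{path}: not valid JSON ({e})", path=str(path)) from e
    if not isinstance(d, dict):
        raise ParseError(f"{path}: top level must be an object", path=str(path))
    return annotation_from_dict(d)


# ---------------------------------------------------------------------------
# terminology (TSV)
# ---------------------------------------------------------------------------

def save_terminology(tree: TerminologyTree, path) -> Path:
    path = Path(path)
    lines = ["id\tlevel\tparent_id\tname\torder"]
    for e in sorted(tree.entries, key=lambda e: (e.order, e.id)):
        lines.append(f"{e.id}\t{e.level}\t{e.parent_id or ''}\t{e.name}\t{e.order}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def load_terminology(path) -> TerminologyTree:
    path = Path(path)
    raw = path.read_text(encoding="utf-8").splitlines()
    rows = [line for line in raw if line.strip()]
    if len(rows) <= 1:
        raise EmptyTerminologyError(f"{path}: no terminology entries", path=str(path))
    header = rows[0].split("\t")
    expected = ["id", "level", "parent_id", "name", "order"]
    if header != expected:
        raise ParseError(f"{path}: header {header} != {expected}", path=str(path))
    entries = []
    for lineno, line in enumerate(rows[1:], start=2):
        parts = line.split("\t")
        if len(parts) != 5:
            raise ParseError(f"{path}:{lineno}: expected 5 columns", line=lineno)
        tid, level, parent, name, order = parts
        try:
            order_i = int(order)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: order {order!r} not an integer", line=lineno)
        entries.append(TermEntry(tid, level, parent or None, name, order_i))
    return TerminologyTree(entries)  # raises StructureError on orphans


# ---------------------------------------------------------------------------
# behavior traces (JSONL with header record)
# ---------------------------------------------------------------------------

def save_trace(trace: Trace, path) -> Path:
    path = Path(path)
    lines = [
        json.dumps(
            {
                "type": "header",
                "wsi_id": trace.wsi_id,
                "annotator_id": trace.annotator_id,
                "screen_px": list(trace.screen_px),
            },
            ensure_ascii=False,
        )
    ]
    for ev in trace.events:
        rec = {"t_ms": int(ev.t_ms), "type": ev.type}
        rec.update(ev.payload)
        lines.append(json.dumps(rec, ensure_ascii=False, sort_keys=True))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def load_trace(path) -> Trace:
    path = Path(path)
    lines = [ln for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty trace file", path=str(path))
    try:
        head = json.loads(lines[0])
    except json.JSONDecodeError as e:
        raise ParseError(f"{path}:1: bad JSON ({e})", line=1) from e
    if head.get("type") != "header":
        raise ParseError(f"{path}:1: first record must be the header", line=1)
    events: list[Event] = []
    prev_t = None
    for lineno, line in enumerate(lines[1:], start=2):
        try:
            rec = json.loads(line)
        except json.JSONDecodeError as e:
            raise ParseError(f"{path}:{lineno}: bad JSON ({e})", line=lineno) from e
        etype = rec.pop("type", None)
        if etype not in EVENT_TYPES:
            raise EventTypeError(f"{path}:{lineno}: unknown event type {etype!r}", line=lineno)
        t_ms = rec.pop("t_ms", None)
        if t_ms is None:
            raise ParseError(f"{path}:{lineno}: event lacks t_ms", line=lineno)
        if prev_t is not None and t_ms < prev_t:
            raise TimeOrderError(
                f"{path}:{lineno}: timestamp {t_ms} < previous {prev_t}", line=lineno
            )
        prev_t = t_ms
        events.append(Event(t_ms=int(t_ms), type=etype, payload=rec))
    return Trace(
        wsi_id=str(_require(head, "wsi_id", "trace header")),
        annotator_id=str(_require(head, "annotator_id", "trace header")),
        screen_px=tuple(_require(head, "screen_px", "trace header")),
        events=events,
    )


# ---------------------------------------------------------------------------
# region geometry (GeoJSON)
# ---------------------------------------------------------------------------

def export_regions_geojson(doc: WSIAnnotation) -> dict:
    """One closed-ring Polygon feature per region, labels in properties."""
    bundle_of: dict[str, str] = {}
    for b in doc.bundles:
        for rid in b.member_region_ids:
            bundle_of.setdefault(rid, b.id)
    features = []
    for r in doc.regions:
        ring = [[int(x), int(y)] for x, y in r.polygon]
        ring.append(ring[0])  # close the ring
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "region_id": r.id,
                    "layer": r.layer,
                    "pencil_shape": r.pencil_shape,
                    "class_label": r.class_label,
                    "subtype_label": r.subtype_label,
                    "reason_labels": list(r.reason_labels),
                    "free_text": r.free_text,
                    "voice_ref": r.voice_ref,
                    "created_ms": int(r.created_ms),
                    "bundle_id": bundle_of.get(r.id),
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def import_regions_geojson(fc: dict, wsi_id: str) -> list[Region]:
    if fc.get("type") != "FeatureCollection":
        raise GeometryError("expected a FeatureCollection")
    regions = []
    for feat in fc.get("features", []):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise GeometryError(
                f"non-polygon geometry {geom.get('type')!r}", geometry=geom.get("type")
            )
        rings = geom.get("coordinates") or []
        if not rings:
            raise GeometryError("polygon without rings")
        ring = rings[0]
        if len(ring) < 4 or ring[0] != ring[-1]:
            raise GeometryError("outer ring must be closed (first == last vertex)")
        poly = [
            (_as_pixel(pt[0], "geojson ring"), _as_pixel(pt[1], "geojson ring"))
            for pt in ring[:-1]
        ]
        props = feat.get("properties") or {}
        regions.append(
            Region(
                id=str(props.get("region_id")),
                wsi_id=wsi_id,
                polygon=poly,
                pencil_shape=props.get("pencil_shape", "curve"),
                layer=props.get("layer", "decision"),
                class_label=props.get("class_label"),
                subtype_label=props.get("subtype_label"),
                reason_labels=[str(t) for t in props.get("reason_labels", [])],
                free_text=props.get("free_text"),
                voice_ref=props.get("voice_ref"),
                created_ms=int(props.get("created_ms", 0)),
            )
        )
    return regions


# ---------------------------------------------------------------------------
# patch manifests (CSV)
# ---------------------------------------------------------------------------

def write_patch_manifest(records: Iterable[dict], path) -> Path:
    """Write patch records as CSV with a fixed column order.

    ``records`` are dicts with at least the manifest columns; extra keys are
    ignored.  ``tissue_frac`` is formatted to six decimals for byte-stable
    output.
    """
    path = Path(path)
    rows = list(records)
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")
    return path


def read_patch_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"wsi_id": str, "label_class": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: manifest missing columns {missing}", path=str(path))
    return df
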