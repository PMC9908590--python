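"""Synthetic desk-scale fixtures.

Generates complete miniature cohorts — slide images, decision-to-reason
annotation documents, behavior traces and ground truth — with controlled
statistical structure, so every pipeline stage is testable without real
whole-slide images.  Textures are procedural (smooth / striped / speckled
per diagnosis class, mixed from two reference stain vectors in optical
density space so stain estimation has signal); they emulate the *structure*
of annotated H&E slides, not their biology.

All randomness flows from one seed through named substreams (images,
labels, traces, perturb), so each artifact can be regenerated independently
and byte-identically.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as pnio
from .behavior import Event, Trace
from .errors import ConfigError
from .schema import (
    Bundle,
    Caption,
    Region,
    TerminologyTree,
    WSIAnnotation,
)

CLASS_IDS = ("c-normal", "c-adenoma", "c-adenocarcinoma")

# reference H&E stain vectors in OD space (hematoxylin, eosin), unit norm
REF_HEMATOXYLIN = np.array([0.65, 0.70, 0.29])
REF_EOSIN = np.array([0.07, 0.99, 0.11])

_STREAMS = {"images": 1, "labels": 2, "traces": 3, "perturb": 4}


def _rng(seed: int, stream: str, *extra: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, _STREAMS[stream], *extra])


def default_terminology() -> TerminologyTree:
    """The bundled three-level terminology fixture (3 / 12 / 77 entries)."""
    from importlib import resources

    path = resources.files("pnkit").joinpath("data/terminology.tsv")
    with resources.as_file(path) as p:
        return pnio.load_terminology(p)


@dataclass
class SynthConfig:
    """Study conditions for the synthetic cohort.

    ``caption_terms_mean`` defaults to 4.4 terms per caption, the typical
    density of reason-term captions in fine-grain colorectal annotation;
    ``class_mix`` is the fraction of (normal, adenoma, adenocarcinoma)
    slides.
    """

    n_wsis: int = 6
    image_size: int = 512
    class_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    regions_per_wsi: tuple[int, int] = (2, 4)
    reason_features_per_region: tuple[int, int] = (1, 3)
    caption_terms_mean: float = 4.4
    bundle_fraction: float = 0.3
    annotator_flip_rate: float = 0.1
    boundary_jitter_px: int = 4
    dwell_lesion_bias: float = 0.8
    trace_duration_s: float = 60.0
    tissue_radius_frac: float = 0.42
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ConfigError("class_mix fractions must sum to 1")
        for r in (self.bundle_fraction, self.annotator_flip_rate, self.dwell_lesion_bias):
            if not 0.0 <= r <= 1.0:
                raise ConfigError("rates must lie in [0, 1]")
        if self.image_size < 128:
            raise ConfigError("image_size must be >= 128 to fit regions")


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _blob_polygon(
    rng: np.random.Generator,
    center: tuple[float, float],
    radius: float,
    n_vertices: int = 16,
    wobble: float = 0.25,
) -> list[tuple[int, int]]:
    angles = np.linspace(0.0, 2 * math.pi, n_vertices, endpoint=False)
    radii = radius * (1.0 + wobble * (rng.random(n_vertices) * 2 - 1))
    pts = [
        (int(round(center[0] + r * math.cos(a))), int(round(center[1] + r * math.sin(a))))
        for a, r in zip(angles, radii)
    ]
    return pts


def _point_in_polygon(rng: np.random.Generator, polygon) -> tuple[float, float]:
    from shapely.geometry import Point, Polygon

    poly = Polygon(polygon)
    minx, miny, maxx, maxy = poly.bounds
    for _ in range(1000):
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if poly.covers(Point(x, y)):
            return x, y
    return poly.representative_point().x, poly.representative_point().y


# ---------------------------------------------------------------------------
# annotation generation
# ---------------------------------------------------------------------------

def _slide_classes(config: SynthConfig) -> list[str]:
    n = config.n_wsis
    counts = [int(round(f * n)) for f in config.class_mix]
    while sum(counts) < n:
        counts[int(np.argmax(config.class_mix))] += 1
    while sum(counts) > n:
        counts[int(np.argmax(counts))] -= 1
    out = []
    for cls, c in zip(CLASS_IDS, counts):
        out.extend([cls] * c)
    return out[:n]


def _caption_terms(
    rng: np.random.Generator, tree: TerminologyTree, subtype_id: str, mean_terms: float
) -> list[str]:
    """Reason-term list of mean length ``mean_terms`` (shifted Poisson, >= 1).

    Terms come from the subtype's reason children; if the draw exceeds the
    vocabulary, free-text tokens (non-terminology) fill the remainder.
    """
    length = 1 + int(rng.poisson(max(mean_terms - 1.0, 0.0)))
    children = [e.id for e in tree.children(subtype_id)]
    rng.shuffle(children)
    terms = children[:length]
    k = 0
    while len(terms) < length:
        terms.append(f"free-text feature {k}")
        k += 1
    return terms


def generate_annotation(
    config: SynthConfig,
    wsi_id: str,
    slide_class: str,
    tree: TerminologyTree,
    annotator_id: str = "synthetic-annotator-a",
) -> WSIAnnotation:
    """One fine-grain document: non-overlapping decision blobs, nested
    reason features, bundles over a fraction of the features."""
    rng = _rng(config.seed, "labels", _stable_hash(wsi_id))
    size = config.image_size
    lo, hi = config.regions_per_wsi
    n_regions = int(rng.integers(lo, hi + 1))
    # non-overlapping placement: jittered grid of candidate centers
    radius = size / 10.0
    margin = size * (0.5 - config.tissue_radius_frac) + radius
    cells = int(math.floor((size - 2 * margin) / (2.4 * radius))) + 1
    candidates = []
    for gy in range(cells):
        for gx in range(cells):
            candidates.append(
                (margin + radius + gx * 2.4 * radius, margin + radius + gy * 2.4 * radius)
            )
    rng.shuffle(candidates)
    if n_regions > len(candidates):
        raise ConfigError(
            f"cannot place {n_regions} regions of radius {radius:.0f} in a "
            f"{size}px slide",
            wsi=wsi_id,
        )
    subtype_ids = [e.id for e in tree.children(slide_class)]

    regions: list[Region] = []
    bundles: list[Bundle] = []
    k = 0
    for r_idx in range(n_regions):
        cx, cy = candidates[r_idx]
        cx += rng.uniform(-0.15, 0.15) * radius
        cy += rng.uniform(-0.15, 0.15) * radius
        subtype = subtype_ids[int(rng.integers(len(subtype_ids)))]
        dec = Region(
            id=f"{wsi_id}-r{k:03d}",
            wsi_id=wsi_id,
            polygon=_blob_polygon(rng, (cx, cy), radius),
            layer="decision",
            class_label=slide_class,
            subtype_label=subtype,
            pencil_shape="curve",
            created_ms=k * 1000,
        )
        k += 1
        regions.append(dec)
        flo, fhi = config.reason_features_per_region
        n_feat = int(rng.integers(flo, fhi + 1))
        feats = []
        for _ in range(n_feat):
            fx, fy = _point_in_polygon(rng, dec.polygon)
            feat = Region(
                id=f"{wsi_id}-r{k:03d}",
                wsi_id=wsi_id,
                polygon=_blob_polygon(rng, (fx, fy), radius * 0.35, n_vertices=10),
                layer="reason",
                class_label=slide_class,
                subtype_label=subtype,
                reason_labels=_caption_terms(rng, tree, subtype, config.caption_terms_mean),
                pencil_shape="brush",
                created_ms=k * 1000,
            )
            k += 1
            regions.append(feat)
            feats.append(feat)
        if len(feats) >= 2 and rng.random() < config.bundle_fraction:
            shared = _caption_terms(rng, tree, subtype, config.caption_terms_mean)
            for f in feats:
                f.reason_labels = []
            bundles.append(
                Bundle(
                    id=f"{wsi_id}-b{len(bundles):02d}",
                    member_region_ids=[f.id for f in feats],
                    caption=Caption(terms=shared),
                )
            )
    return WSIAnnotation(
        wsi_id=wsi_id,
        annotator_id=annotator_id,
        phase="fine",
        slide_caption=tree.get(slide_class).name,
        regions=regions,
        bundles=bundles,
        audit_status="submitted",
    )


def _stable_hash(text: str) -> int:
    h = 0
    for ch in text:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


# ---------------------------------------------------------------------------
# image generation
# ---------------------------------------------------------------------------

def _render_stains(h_conc: np.ndarray, e_conc: np.ndarray) -> np.ndarray:
    od = np.stack([h_conc, e_conc], axis=-1) @ np.stack([REF_HEMATOXYLIN, REF_EOSIN])
    img = 255.0 * np.power(10.0, -od)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate_image(
    config: SynthConfig, wsi_id: str, slide_class: str
) -> tuple[np.ndarray, float]:
    """Procedural slide: white background, one tissue disc textured by class.

    normal -> smooth eosin wash; adenoma -> stained stripes;
    adenocarcinoma -> dense hematoxylin speckles.  Returns the image and the
    painted tissue fraction (ground truth for mask recovery tests).
    """
    from PIL import Image, ImageDraw

    rng = _rng(config.seed, "images", _stable_hash(wsi_id))
    size = config.image_size
    tissue_poly = _blob_polygon(
        rng, (size / 2, size / 2), size * config.tissue_radius_frac, n_vertices=24, wobble=0.08
    )
    mask_img = Image.new("1", (size, size), 0)
    ImageDraw.Draw(mask_img).polygon(tissue_poly, fill=1)
    tissue = np.asarray(mask_img, dtype=bool)

    yy, xx = np.mgrid[0:size, 0:size]
    noise = rng.normal(0.0, 0.02, (size, size))
    if slide_class == "c-normal":
        h = 0.12 + noise
        e = 0.35 + rng.normal(0.0, 0.03, (size, size))
    elif slide_class == "c-adenoma":
        stripes = 0.5 * (1 + np.sin(2 * math.pi * xx / 24.0))
        h = 0.15 + 0.35 * stripes + noise
        e = 0.45 - 0.20 * stripes + noise
    else:  # adenocarcinoma: speckled
        h = 0.18 + noise
        e = 0.30 + noise
        n_dots = (size // 8) ** 2
        cx = rng.integers(0, size, n_dots)
        cy = rng.integers(0, size, n_dots)
        dots = np.zeros((size, size))
        dots[cy, cx] = 1.0
        from scipy import ndimage

        dots = ndimage.gaussian_filter(dots, sigma=1.5)
        m = dots.max()
        if m > 0:
            dots = dots / m
        h = h + 0.9 * dots
    img = _render_stains(np.clip(h, 0, None), np.clip(e, 0, None))
    out = np.full((size, size, 3), 255, dtype=np.uint8)
    out[tissue] = img[tissue]
    return out, float(tissue.mean())


# ---------------------------------------------------------------------------
# annotator perturbation
# ---------------------------------------------------------------------------

def perturb_annotator(
    doc: WSIAnnotation,
    tree: TerminologyTree,
    flip_rate: float,
    jitter_px: int = 0,
    seed: int = 0,
    annotator_id: str = "synthetic-annotator-b",
) -> tuple[WSIAnnotation, list[dict]]:
    """Simulated second annotator: independent label flips plus vertex jitter.

    Each region's class label flips to a uniformly different class with
    probability ``flip_rate`` (subtype and reason labels are re-drawn under
    the new class to keep lineage valid); every vertex is shifted by a
    uniform integer offset in ``[-jitter_px, jitter_px]``.  The edit log
    records every change and is the oracle for audit-diff tests.
    """
    rng = _rng(seed, "perturb", _stable_hash(doc.wsi_id))
    out = copy.deepcopy(doc)
    out.annotator_id = annotator_id
    log: list[dict] = []
    for r in out.regions:
        if rng.random() < flip_rate:
            others = [c for c in CLASS_IDS if c != r.class_label]
            new_class = others[int(rng.integers(len(others)))]
            log.append(
                {"action": "relabel", "region_id": r.id,
                 "field": "class_label", "old": r.class_label, "new": new_class}
            )
            r.class_label = new_class
            subs = [e.id for e in tree.children(new_class)]
            new_sub = subs[int(rng.integers(len(subs)))]
            if r.subtype_label is not None:
                log.append(
                    {"action": "relabel", "region_id": r.id,
                     "field": "subtype_label", "old": r.subtype_label, "new": new_sub}
                )
                r.subtype_label = new_sub
            if r.reason_labels:
                old = list(r.reason_labels)
                sub_rng = np.random.default_rng(
                    [seed & 0x7FFFFFFF, _STREAMS["perturb"], _stable_hash(r.id)]
                )
                r.reason_labels = _caption_terms(sub_rng, tree, new_sub, len(old))
                log.append(
                    {"action": "relabel", "region_id": r.id,
                     "field": "reason_labels", "old": old, "new": list(r.reason_labels)}
                )
        if jitter_px > 0:
            r.polygon = [
                (
                    max(0, int(x + rng.integers(-jitter_px, jitter_px + 1))),
                    max(0, int(y + rng.integers(-jitter_px, jitter_px + 1))),
                )
                for x, y in r.polygon
            ]
            log.append({"action": "jitter", "region_id": r.id, "max_px": jitter_px})
    return out, log


# ---------------------------------------------------------------------------
# trace generation
# ---------------------------------------------------------------------------

def generate_trace(
    doc: WSIAnnotation,
    config: SynthConfig,
    slide_size: tuple[int, int] | None = None,
    screen_px: tuple[int, int] = (1920, 1080),
    magnification: float = 8.0,
) -> Trace:
    """Behavior trace whose dwell concentrates inside lesion regions.

    FOV centers land inside a uniformly chosen lesion polygon with
    probability ``dwell_lesion_bias`` and uniformly outside all lesions
    otherwise; intervals are one second each, timestamps strictly
    increasing.  A trailing voice_stop event closes the final interval
    without moving the viewport.
    """
    from shapely.geometry import Point, Polygon

    rng = _rng(config.seed, "traces", _stable_hash(doc.wsi_id))
    size = slide_size or (config.image_size, config.image_size)
    lesions = [r for r in doc.regions if r.layer == "decision"]
    polys = [Polygon(r.polygon) for r in lesions]
    n_moves = max(2, int(config.trace_duration_s))
    events = []
    t = 0
    for k in range(n_moves):
        if lesions and rng.random() < config.dwell_lesion_bias:
            which = int(rng.integers(len(lesions)))
            x, y = _point_in_polygon(rng, lesions[which].polygon)
        else:
            for _ in range(200):
                x = rng.uniform(0, size[0])
                y = rng.uniform(0, size[1])
                if not any(p.covers(Point(x, y)) for p in polys):
                    break
        events.append(
            Event(t_ms=t, type="fov_center_change", payload={"x": round(x, 1), "y": round(y, 1)})
        )
        if k == 0:
            t += 1
            events.append(Event(t_ms=t, type="magnification", payload={"factor": magnification}))
            t += 999
        else:
            t += 1000
    events.append(Event(t_ms=t, type="voice_stop", payload={}))
    return Trace(
        wsi_id=doc.wsi_id,
        annotator_id=doc.annotator_id,
        screen_px=screen_px,
        events=events,
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    slide_classes: dict[str, str]
    tissue_fractions: dict[str, float]
    seed: int

    def to_dict(self) -> dict:
        return {
            "slide_classes": dict(sorted(self.slide_classes.items())),
            "tissue_fractions": {
                k: round(v, 6) for k, v in sorted(self.tissue_fractions.items())
            },
            "seed": self.seed,
        }


def generate_cohort(config: SynthConfig, out_dir) -> GroundTruth:
    """Write a complete fixture directory: per-slide PNG image, annotation
    JSON and trace JSONL, plus the terminology TSV and ground truth JSON.
    Deterministic under ``config.seed``."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tree = default_terminology()
    pnio.save_terminology(tree, out_dir / "terminology.tsv")
    classes = _slide_classes(config)
    gt = GroundTruth(slide_classes={}, tissue_fractions={}, seed=config.seed)
    for k, slide_class in enumerate(classes):
        wsi_id = f"wsi{k:03d}"
        img, tissue_frac = generate_image(config, wsi_id, slide_class)
        Image.fromarray(img).save(out_dir / f"{wsi_id}.png", format="PNG")
        doc = generate_annotation(config, wsi_id, slide_class, tree)
        doc.events_ref = f"{wsi_id}.trace.jsonl"
        pnio.save_annotation(doc, out_dir / f"{wsi_id}.json")
        trace = generate_trace(doc, config)
        pnio.save_trace(trace, out_dir / f"{wsi_id}.trace.jsonl")
        gt.slide_classes[wsi_id] = slide_class
        gt.tissue_fractions[wsi_id] = tissue_frac
    (out_dir / "ground_truth.json").write_text(
        json.dumps(gt.to_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return gt
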