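"""Inter-annotator agreement and evaluation metrics.

The three-level consistency protocol compares two annotators' documents for
one slide at increasing resolution:

* slide level — agreement of the overall diagnosis class,
* patch level — Cohen's kappa over central-pixel labels on a shared grid
  (classification labels and subtype labels separately),
* pixel level — Dice overlap of the rasterized same-label lesion area,

plus BLEU between the captions of IoU-matched feature regions.  The same
module hosts the audit diff (IoU-matched add/remove/modify report) and the
confusion-matrix classification report used for model evaluation.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import PnkitError
from .schema import Caption, Region, TerminologyTree, WSIAnnotation, expand_bundles
from .tiling import DEFAULT_PRIORITY, PatchGridSpec, assign_patch_label

BACKGROUND = "__none__"


# ---------------------------------------------------------------------------
# Cohen's kappa
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KappaResult:
    kappa: float
    p_o: float
    p_e: float
    n: int
    degenerate: bool = False


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> KappaResult:
    """Chance-corrected agreement between two raters.

    ``p_o`` is the fraction of equal labels, ``p_e`` the product-of-marginals
    chance agreement, and kappa = (p_o - p_e) / (1 - p_e).  When both raters
    use a single identical label, p_e = 1 and kappa is defined as 1 with the
    ``degenerate`` flag set.
    """
    if len(labels_a) != len(labels_b):
        raise PnkitError("label lists must have equal length")
    n = len(labels_a)
    if n == 0:
        raise PnkitError("need at least one unit")
    p_o = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    ca, cb = Counter(labels_a), Counter(labels_b)
    p_e = sum(ca[k] * cb.get(k, 0) for k in ca) / (n * n)
    if p_e >= 1.0:
        return KappaResult(kappa=1.0, p_o=p_o, p_e=1.0, n=n, degenerate=True)
    return KappaResult(kappa=(p_o - p_e) / (1.0 - p_e), p_o=p_o, p_e=p_e, n=n)


# ---------------------------------------------------------------------------
# Dice
# ---------------------------------------------------------------------------

def dice_coefficient(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """``2|A∩B| / (|A|+|B|)``; two empty masks agree perfectly (1.0)."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise PnkitError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def per_label_dice(
    map_a: np.ndarray, map_b: np.ndarray, labels: Iterable
) -> dict:
    return {k: dice_coefficient(map_a == k, map_b == k) for k in labels}


# ---------------------------------------------------------------------------
# BLEU
# ---------------------------------------------------------------------------

def tokenize_caption(
    caption: Caption | str | Sequence[str], tree: TerminologyTree | None = None
) -> list[str]:
    """Canonical caption tokenization: terminology ids are detokenized to
    their display names, then everything is lowercased, commas become
    separators, trailing periods are stripped, and whitespace splits."""
    if isinstance(caption, Caption):
        parts = list(caption.terms)
        if caption.diagnosis_phrase:
            parts.append(caption.diagnosis_phrase)
    elif isinstance(caption, str):
        parts = [caption]
    else:
        parts = list(caption)
    words: list[str] = []
    for part in parts:
        if tree is not None and part in tree:
            part = tree.get(part).name
        text = part.replace(",", " ").lower()
        for tok in text.split():
            tok = tok.strip(".")
            if tok:
                words.append(tok)
    return words


def _ngrams(tokens: Sequence[str], n: int) -> Counter:
    return Counter(tuple(tokens[k : k + n]) for k in range(len(tokens) - n + 1))


def bleu_n(
    candidate: Sequence[str], references: Sequence[Sequence[str]], n: int
) -> float:
    """Clipped n-gram precision: candidate counts clipped at the maximum
    count of the same n-gram in any reference.  A candidate shorter than
    ``n`` scores 0."""
    if n < 1:
        raise PnkitError("n must be >= 1")
    if not candidate:
        raise PnkitError("empty candidate")
    cand = _ngrams(candidate, n)
    total = sum(cand.values())
    if total == 0:
        return 0.0
    max_ref: Counter = Counter()
    for ref in references:
        for g, c in _ngrams(ref, n).items():
            if c > max_ref[g]:
                max_ref[g] = c
    clipped = sum(min(c, max_ref[g]) for g, c in cand.items())
    return clipped / total


def bleu_composite(
    candidate: Sequence[str],
    references: Sequence[Sequence[str]],
    max_n: int = 4,
    smoothing: bool = False,
) -> float:
    """Brevity penalty times the geometric mean of bleu_1..bleu_max_n.

    Without smoothing (the default) any zero precision zeroes the score;
    with ``smoothing`` an add-one is applied to the clipped count and total
    of orders above 1, for diagnostics on very short captions.
    """
    if not candidate:
        raise PnkitError("empty candidate")
    c = len(candidate)
    r = min((len(ref) for ref in references), key=lambda L: (abs(L - c), L))
    bp = 1.0 if c >= r else math.exp(1.0 - r / c)
    logs = []
    for n in range(1, max_n + 1):
        p = bleu_n(candidate, references, n)
        if p == 0.0:
            if not smoothing or n == 1:
                return 0.0
            cand_total = max(len(candidate) - n + 1, 0)
            p = 1.0 / (cand_total + 1)
        logs.append(math.log(p))
    return bp * math.exp(sum(logs) / max_n)


# ---------------------------------------------------------------------------
# document comparison
# ---------------------------------------------------------------------------

@dataclass
class AgreementReport:
    wsi_id: str
    slide_classes: tuple[str | None, str | None]
    slide_agree: bool
    patch_kappa_class: KappaResult | None
    patch_kappa_subtype: KappaResult | None
    dice_class: dict
    dice_subtype: dict
    caption_bleu: dict  # n -> mean BLEU over matched region pairs
    n_caption_pairs: int


def _slide_class(doc: WSIAnnotation, priority: Sequence[str]) -> str | None:
    rank = {c: k for k, c in enumerate(priority)}
    classes = [r.class_label for r in doc.regions if r.layer == "decision"]
    if not classes:
        return None
    return min(classes, key=lambda c: rank.get(c, len(priority)))


def _doc_bounds(*docs: WSIAnnotation) -> tuple[int, int]:
    xmax = ymax = 0
    for doc in docs:
        for r in doc.regions:
            for x, y in r.polygon:
                xmax, ymax = max(xmax, x), max(ymax, y)
    return xmax + 1, ymax + 1


def rasterize_class_map(
    doc: WSIAnnotation,
    size: tuple[int, int],
    downsample: int = 4,
    priority: Sequence[str] = DEFAULT_PRIORITY,
    attr: str = "class_label",
) -> np.ndarray:
    """Rasterize decision regions to a label map at ``1/downsample`` scale.

    Higher-priority classes paint last, i.e. win overlaps — the same rule
    the central-pixel patch labeling applies.
    """
    from PIL import Image, ImageDraw

    w = max(1, -(-size[0] // downsample))
    h = max(1, -(-size[1] // downsample))
    img = Image.new("I", (w, h), 0)
    draw = ImageDraw.Draw(img)
    rank = {c: k for k, c in enumerate(priority)}
    regions = [r for r in doc.regions if r.layer == "decision"]
    order = sorted(
        enumerate(regions),
        key=lambda t: (-rank.get(t[1].class_label, len(priority)), -t[0]),
    )
    values: list[str | None] = [None]
    codes: dict[str, int] = {}
    for _, r in order:
        key = getattr(r, attr)
        if key is None:
            continue
        code = codes.setdefault(key, len(values))
        if code == len(values):
            values.append(key)
        pts = [(x / downsample, y / downsample) for x, y in r.polygon]
        draw.polygon(pts, fill=code)
    arr = np.asarray(img)
    out = np.empty(arr.shape, dtype=object)
    for code, val in enumerate(values):
        out[arr == code] = val
    return out


def compare_annotations(
    doc_a: WSIAnnotation,
    doc_b: WSIAnnotation,
    grid: PatchGridSpec = PatchGridSpec(),
    tree: TerminologyTree | None = None,
    image_size: tuple[int, int] | None = None,
    priority: Sequence[str] = DEFAULT_PRIORITY,
    include_background: bool = False,
    dice_downsample: int = 4,
    iou_threshold: float = 0.0,
) -> AgreementReport:
    """Three-level agreement between two documents for the same slide.

    Patch-level kappa is computed over grid centers labeled by at least one
    annotator (both-background patches excluded unless
    ``include_background``); the label of an annotator who left a patch
    unlabeled is a distinct background category.  Pixel-level Dice is per
    shared label on rasterized class maps.  Caption BLEU is averaged over
    reason-region pairs matched greedily by descending IoU.
    """
    if doc_a.wsi_id != doc_b.wsi_id:
        raise PnkitError(
            f"documents describe different slides: {doc_a.wsi_id!r} vs {doc_b.wsi_id!r}"
        )
    size = image_size or _doc_bounds(doc_a, doc_b)

    cls_a, cls_b = _slide_class(doc_a, priority), _slide_class(doc_b, priority)

    dec_a = [r for r in doc_a.regions if r.layer == "decision"]
    dec_b = [r for r in doc_b.regions if r.layer == "decision"]
    la_cls, lb_cls, la_sub, lb_sub = [], [], [], []
    step, ps = grid.step, grid.patch_size
    for j in range(max(1, -(-size[1] // step))):
        for i in range(max(1, -(-size[0] // step))):
            center = grid.center(i, j)
            a = assign_patch_label(center, dec_a, priority)
            b = assign_patch_label(center, dec_b, priority)
            if a is None and b is None and not include_background:
                continue
            la_cls.append(a[0] if a else BACKGROUND)
            lb_cls.append(b[0] if b else BACKGROUND)
            la_sub.append((a[1] or a[0]) if a else BACKGROUND)
            lb_sub.append((b[1] or b[0]) if b else BACKGROUND)
    kappa_cls = cohen_kappa(la_cls, lb_cls) if la_cls else None
    kappa_sub = cohen_kappa(la_sub, lb_sub) if la_sub else None

    map_a = rasterize_class_map(doc_a, size, dice_downsample, priority, "class_label")
    map_b = rasterize_class_map(doc_b, size, dice_downsample, priority, "class_label")
    labels_cls = sorted(
        {v for v in set(map_a.ravel()) | set(map_b.ravel()) if v is not None}
    )
    dice_cls = per_label_dice(map_a, map_b, labels_cls)
    sub_a = rasterize_class_map(doc_a, size, dice_downsample, priority, "subtype_label")
    sub_b = rasterize_class_map(doc_b, size, dice_downsample, priority, "subtype_label")
    labels_sub = sorted(
        {v for v in set(sub_a.ravel()) | set(sub_b.ravel()) if v is not None}
    )
    dice_sub = per_label_dice(sub_a, sub_b, labels_sub)

    pairs = _match_caption_pairs(doc_a, doc_b, iou_threshold)
    bleu_scores: dict[int, float] = {}
    if pairs:
        for n in (1,):
            vals = []
            for cap_a, cap_b in pairs:
                ta = tokenize_caption(cap_a, tree)
                tb = tokenize_caption(cap_b, tree)
                if not ta or not tb:
                    continue
                vals.append(bleu_n(ta, [tb], n))
            if vals:
                bleu_scores[n] = float(np.mean(vals))
    return AgreementReport(
        wsi_id=doc_a.wsi_id,
        slide_classes=(cls_a, cls_b),
        slide_agree=cls_a == cls_b,
        patch_kappa_class=kappa_cls,
        patch_kappa_subtype=kappa_sub,
        dice_class=dice_cls,
        dice_subtype=dice_sub,
        caption_bleu=bleu_scores,
        n_caption_pairs=len(pairs),
    )


def _region_iou(a: Region, b: Region) -> float:
    from shapely.geometry import Polygon

    pa = Polygon(a.polygon).buffer(0)
    pb = Polygon(b.polygon).buffer(0)
    inter = pa.intersection(pb).area
    union = pa.union(pb).area
    return inter / union if union > 0 else 0.0


def _match_caption_pairs(
    doc_a: WSIAnnotation, doc_b: WSIAnnotation, iou_threshold: float
) -> list[tuple[Caption, Caption]]:
    caps_a = dict(expand_bundles(doc_a))
    caps_b = dict(expand_bundles(doc_b))
    ra = [r for r in doc_a.regions if r.id in caps_a and caps_a[r.id].term_count > 0]
    rb = [r for r in doc_b.regions if r.id in caps_b and caps_b[r.id].term_count > 0]
    scored = []
    for ia, a in enumerate(ra):
        for ib, b in enumerate(rb):
            iou = _region_iou(a, b)
            if iou > iou_threshold:
                scored.append((iou, ia, ib))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for iou, ia, ib in scored:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        pairs.append((caps_a[ra[ia].id], caps_b[rb[ib].id]))
    return pairs


# ---------------------------------------------------------------------------
# audit diff
# ---------------------------------------------------------------------------

@dataclass
class RegionChange:
    old_id: str
    new_id: str
    changes: dict  # field -> (old, new)


@dataclass
class AuditReport:
    added: list[str] = field(default_factory=list)
    removed: list[str] = field(default_factory=list)
    modified: list[RegionChange] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not (self.added or self.removed or self.modified)


_AUDIT_FIELDS = ("class_label", "subtype_label", "reason_labels", "free_text")


def audit_diff(
    old_doc: WSIAnnotation, new_doc: WSIAnnotation, iou_threshold: float = 0.5
) -> AuditReport:
    """IoU-matched document diff used to formalize the audit pass.

    Regions are matched greedily by descending polygon IoU above the
    threshold; unmatched old regions are removed, unmatched new ones added,
    and matched regions with differing labels/captions are modified.
    """
    if old_doc.wsi_id != new_doc.wsi_id:
        raise PnkitError("audit_diff requires documents for the same slide")
    old_regions = list(old_doc.regions)
    new_regions = list(new_doc.regions)
    scored = []
    for io_, ro in enumerate(old_regions):
        for in_, rn in enumerate(new_regions):
            if ro.layer != rn.layer:
                continue
            iou = _region_iou(ro, rn)
            if iou >= iou_threshold:
                scored.append((iou, io_, in_))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    matched_old: dict[int, int] = {}
    matched_new: set[int] = set()
    for iou, io_, in_ in scored:
        if io_ in matched_old or in_ in matched_new:
            continue
        matched_old[io_] = in_
        matched_new.add(in_)
    report = AuditReport()
    caps_old = dict(expand_bundles(old_doc))
    caps_new = dict(expand_bundles(new_doc))
    for io_, ro in enumerate(old_regions):
        if io_ not in matched_old:
            report.removed.append(ro.id)
            continue
        rn = new_regions[matched_old[io_]]
        changes: dict = {}
        for f in _AUDIT_FIELDS:
            vo, vn = getattr(ro, f), getattr(rn, f)
            if vo != vn:
                changes[f] = (vo, vn)
        co = caps_old.get(ro.id)
        cn = caps_new.get(rn.id)
        if (co.terms if co else None) != (cn.terms if cn else None):
            changes["caption"] = (co.terms if co else None, cn.terms if cn else None)
        if changes:
            report.modified.append(RegionChange(ro.id, rn.id, changes))
    for in_, rn in enumerate(new_regions):
        if in_ not in matched_new:
            report.added.append(rn.id)
    return report


# ---------------------------------------------------------------------------
# confusion-matrix evaluation
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """Rows = ground truth, columns = prediction."""

    labels: list[str]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.labels), len(self.labels)):
            raise PnkitError("counts must be KxK for K labels")
        if (self.counts < 0).any():
            raise PnkitError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise PnkitError("confusion matrix is empty")

    @classmethod
    def from_pairs(cls, truth: Sequence[str], pred: Sequence[str], labels=None):
        labels = list(labels) if labels else sorted(set(truth) | set(pred))
        idx = {k: i for i, k in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
        for t, p in zip(truth, pred):
            counts[idx[t], idx[p]] += 1
        return cls(labels, counts)


@dataclass
class ClassificationReport:
    labels: list[str]
    recall: dict       # label -> float or None (undefined on empty row)
    precision: dict    # label -> float or None (undefined on empty column)
    accuracy: float


def classification_report(cm: ConfusionMatrix) -> ClassificationReport:
    """Per-class recall/precision and overall accuracy from a confusion
    matrix.  Zero denominators yield ``None`` (undefined), never 0."""
    counts = cm.counts
    total = int(counts.sum())
    recall = {}
    precision = {}
    for k, label in enumerate(cm.labels):
        row = int(counts[k].sum())
        col = int(counts[:, k].sum())
        recall[label] = (int(counts[k, k]) / row) if row > 0 else None
        precision[label] = (int(counts[k, k]) / col) if col > 0 else None
    accuracy = float(np.trace(counts)) / total
    return ClassificationReport(
        labels=list(cm.labels), recall=recall, precision=precision, accuracy=accuracy
    )
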