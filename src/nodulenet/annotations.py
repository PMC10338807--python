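"""Per-reader nodule annotations: parsing, grouping, cohort filters and
label generation.

Each nodule in an LIDC-style dataset is annotated by up to four
radiologists, each supplying a segmentation, a 1-5 malignancy rating and
eight semantic-feature ratings.  Two label views are derived:

* the *individual* label treats every reader's annotation as its own case
  (ratings 1-3 benign, 4-5 malignant);
* the *panel* label averages the readers' ratings per nodule (mean < 3
  benign, > 3 malignant, exactly 3 excluded).

Semantic features are binarized per feature: calcification level 6 versus
levels 1-5; every other feature levels 4-5 versus 1-3 (for the 1-4
internal-structure scale, level 4 alone forms the upper category).

Two document dialects are supported: a simplified LIDC-style XML (reading
sessions with per-reader characteristics and slice-wise ROI contours) and
the JSON manifest written by :mod:`nodulenet.synthetic`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from xml.etree import ElementTree

import numpy as np

from .network import SEMANTIC_FEATURES

#: inclusive rating range per semantic feature
FEATURE_RANGES = {f: (1, 5) for f in SEMANTIC_FEATURES}
FEATURE_RANGES["internalStructure"] = (1, 4)
FEATURE_RANGES["calcification"] = (1, 6)

BENIGN, MALIGNANT = 0, 1
EXCLUDED = "EXCLUDED"


class AnnotationError(ValueError):
    """Malformed document or out-of-range rating."""


@dataclass
class ReaderAnnotation:
    reader_id: str
    nodule_key: str | None
    scan_id: str
    center: tuple[int, int, int]
    mask: np.ndarray                      # binary, scan voxel grid
    malignancy: int
    semantic_scores: dict[str, int]

    def validate(self):
        if self.malignancy not in range(1, 6):
            raise AnnotationError(
                f"malignancy {self.malignancy} outside 1-5 "
                f"(reader {self.reader_id})")
        missing = set(SEMANTIC_FEATURES) - set(self.semantic_scores)
        if missing:
            raise AnnotationError(f"missing semantic scores: {sorted(missing)}")
        for feat, score in self.semantic_scores.items():
            lo, hi = FEATURE_RANGES.get(feat, (None, None))
            if lo is None:
                raise AnnotationError(f"unknown semantic feature {feat!r}")
            if not lo <= score <= hi:
                raise AnnotationError(
                    f"{feat} score {score} outside {lo}-{hi}")
        if self.mask is not None:
            vals = np.unique(self.mask)
            if not np.all(np.isin(vals, (0, 1))):
                raise AnnotationError("mask is not strictly binary")
        return self


@dataclass
class NoduleRecord:
    nodule_id: str
    scan_id: str
    slice_thickness: float | None
    annotations: list[ReaderAnnotation]
    ambiguous: bool = False

    @property
    def n_readers(self) -> int:
        return len({a.reader_id for a in self.annotations})


@dataclass(frozen=True)
class MatchConfig:
    """Nodule-identity matching for documents without reliable keys."""
    distance_threshold: float = 5.0    # voxels; centers closer are one nodule
    ambiguity_distance: float = 20.0   # same-key centers farther are ambiguous


# ---------------------------------------------------------------------------
# label rules
# ---------------------------------------------------------------------------

def individual_label(malignancy: int) -> int:
    """1-3 -> benign (0); 4-5 -> malignant (1)."""
    if malignancy not in range(1, 6):
        raise AnnotationError(f"malignancy {malignancy} outside 1-5")
    return MALIGNANT if malignancy >= 4 else BENIGN


def panel_label(ratings) -> int | str:
    """Mean rating < 3 -> benign, > 3 -> malignant, == 3 -> EXCLUDED."""
    ratings = list(ratings)
    if not ratings:
        raise AnnotationError("panel label requires at least one rating")
    for r in ratings:
        if r not in range(1, 6):
            raise AnnotationError(f"rating {r} outside 1-5")
    mean = sum(ratings) / len(ratings)
    if mean < 3:
        return BENIGN
    if mean > 3:
        return MALIGNANT
    return EXCLUDED


def binarize_semantic(feature: str, score: int) -> int:
    """Calcification: 6 -> 1, 1-5 -> 0.  Other features: 4+ -> 1, 1-3 -> 0."""
    lo, hi = FEATURE_RANGES.get(feature, (None, None))
    if lo is None:
        raise AnnotationError(f"unknown semantic feature {feature!r}")
    if not lo <= score <= hi:
        raise AnnotationError(f"{feature} score {score} outside {lo}-{hi}")
    if feature == "calcification":
        return int(score == 6)
    return int(score >= 4)


def semantic_labels(scores: dict[str, int]) -> dict[str, int]:
    return {f: binarize_semantic(f, scores[f]) for f in SEMANTIC_FEATURES}


# ---------------------------------------------------------------------------
# grouping and cohort filters
# ---------------------------------------------------------------------------

def _center_distance(a, b) -> float:
    return math.dist(a, b)


def group_to_nodules(annotations: list[ReaderAnnotation],
                     matching: MatchConfig = MatchConfig(),
                     slice_thickness: dict[str, float] | float | None = None
                     ) -> list[NoduleRecord]:
    """Group annotations of the same physical nodule.

    Explicit ``nodule_key`` values win; key groups whose centers spread
    farther than ``ambiguity_distance`` are flagged ambiguous rather than
    split.  Keyless annotations are clustered greedily by centroid distance
    (``distance_threshold``).  Ambiguity is flagged, never raised.
    """
    def thickness(scan_id):
        if isinstance(slice_thickness, dict):
            return slice_thickness.get(scan_id)
        return slice_thickness

    records: list[NoduleRecord] = []
    keyed: dict[tuple[str, str], list[ReaderAnnotation]] = {}
    free: list[ReaderAnnotation] = []
    for ann in annotations:
        if ann.nodule_key is not None:
            keyed.setdefault((ann.scan_id, ann.nodule_key), []).append(ann)
        else:
            free.append(ann)
    for (scan_id, key), group in keyed.items():
        spread = max((_center_distance(a.center, b.center)
                      for a in group for b in group), default=0.0)
        records.append(NoduleRecord(
            nodule_id=f"{scan_id}:{key}", scan_id=scan_id,
            slice_thickness=thickness(scan_id), annotations=group,
            ambiguous=spread > matching.ambiguity_distance))
    # greedy centroid clustering for keyless annotations, per scan
    clusters: list[list[ReaderAnnotation]] = []
    for ann in free:
        for cl in clusters:
            if cl[0].scan_id != ann.scan_id:
                continue
            centroid = np.mean([a.center for a in cl], axis=0)
            if _center_distance(centroid, ann.center) <= \
                    matching.distance_threshold:
                cl.append(ann)
                break
        else:
            clusters.append([ann])
    for i, cl in enumerate(clusters):
        records.append(NoduleRecord(
            nodule_id=f"{cl[0].scan_id}:auto{i}", scan_id=cl[0].scan_id,
            slice_thickness=thickness(cl[0].scan_id), annotations=cl))
    return records


def filter_individual_cohort(records: list[NoduleRecord]
                             ) -> list[ReaderAnnotation]:
    """Individual-label cohort: records read by >= 3 radiologists on scans
    with slice thickness < 3 mm; every retained annotation is its own case.
    """
    kept: list[ReaderAnnotation] = []
    for rec in records:
        if rec.slice_thickness is None:
            raise AnnotationError(
                f"record {rec.nodule_id} has no slice thickness")
        if rec.ambiguous:
            continue
        if rec.n_readers >= 3 and rec.slice_thickness < 3.0:
            kept.extend(rec.annotations)
    return kept


def filter_panel_cohort(records: list[NoduleRecord]) -> list[NoduleRecord]:
    """Panel-label cohort: unambiguous records whose mean rating is not 3."""
    return [rec for rec in records
            if not rec.ambiguous
            and panel_label([a.malignancy for a in rec.annotations])
            != EXCLUDED]


# ---------------------------------------------------------------------------
# document parsing
# ---------------------------------------------------------------------------

def parse_annotations(document: str | Path,
                      masks_root: str | Path | None = None
                      ) -> list[ReaderAnnotation]:
    """Parse a JSON manifest or LIDC-style XML into annotations.

    The dialect is chosen by file suffix (``.json`` vs ``.xml``).  JSON
    manifests reference masks as NIfTI files relative to the manifest (or
    ``masks_root``); XML documents carry slice-wise ROI contours that are
    rasterized to binary masks on the scan grid.
    """
    path = Path(document)
    if path.suffix == ".json":
        return _parse_manifest(path, masks_root)
    if path.suffix == ".xml":
        return _parse_xml(path)
    raise AnnotationError(f"unrecognised document type: {path.name}")


def _parse_manifest(path: Path, masks_root=None) -> list[ReaderAnnotation]:
    import nibabel as nib

    root = Path(masks_root) if masks_root else path.parent
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise AnnotationError(f"malformed JSON manifest {path.name}: {e}")
    out = []
    for i, rec in enumerate(doc.get("annotations", [])):
        try:
            mask = None
            if rec.get("mask"):
                mask = np.asarray(
                    nib.load(root / rec["mask"]).dataobj).astype(np.uint8)
            ann = ReaderAnnotation(
                reader_id=str(rec["reader_id"]),
                nodule_key=rec.get("nodule_key"),
                scan_id=str(rec.get("scan_id", "scan")),
                center=tuple(int(c) for c in rec["center"]),
                mask=mask,
                malignancy=int(rec["malignancy"]),
                semantic_scores={k: int(v) for k, v in
                                 rec["semantic_scores"].items()},
            ).validate()
        except KeyError as e:
            raise AnnotationError(
                f"annotation #{i} in {path.name} missing field {e}")
        out.append(ann)
    return out


def _parse_xml(path: Path) -> list[ReaderAnnotation]:
    """Parse the simplified LIDC-style XML dialect.

    Layout: ``<annotationFile>`` with a ``<header>`` (scan id, volume shape,
    voxel spacing, slice thickness) and one ``<readingSession>`` per reader,
    each holding ``<nodule>`` elements with ``<characteristics>`` and
    slice-wise ``<roi>`` contours (``edgeMap`` vertices in voxel
    coordinates).  Contours are filled per slice with a polygon rasteriser.
    """
    from skimage.draw import polygon as fill_polygon

    try:
        tree = ElementTree.parse(path)
    except ElementTree.ParseError as e:
        raise AnnotationError(f"malformed XML {path.name}: {e}")
    root = tree.getroot()
    header = root.find("header")
    if header is None:
        raise AnnotationError(f"{path.name}: missing <header> element")
    scan_id = header.findtext("scanId", default="scan")
    shape_txt = header.findtext("volumeShape")
    if shape_txt is None:
        raise AnnotationError(f"{path.name}: header lacks <volumeShape>")
    shape = tuple(int(v) for v in shape_txt.split())
    out = []
    for session in root.iter("readingSession"):
        reader = session.findtext("radiologistId")
        if reader is None:
            raise AnnotationError(
                f"{path.name}: readingSession lacks <radiologistId>")
        for nod in session.iter("nodule"):
            key = nod.findtext("noduleId")
            chars = nod.find("characteristics")
            if chars is None:
                raise AnnotationError(
                    f"{path.name}: nodule {key!r} lacks <characteristics>")
            scores = {}
            for feat in SEMANTIC_FEATURES:
                txt = chars.findtext(feat)
                if txt is None:
                    raise AnnotationError(
                        f"{path.name}: nodule {key!r} lacks <{feat}>")
                scores[feat] = int(txt)
            mal_txt = chars.findtext("malignancy")
            if mal_txt is None:
                raise AnnotationError(
                    f"{path.name}: nodule {key!r} lacks <malignancy>")
            mask = np.zeros(shape, dtype=np.uint8)
            for roi in nod.iter("roi"):
                z = int(round(float(roi.findtext("sliceIndex", "0"))))
                xs, ys = [], []
                for edge in roi.iter("edgeMap"):
                    xs.append(int(edge.findtext("xCoord")))
                    ys.append(int(edge.findtext("yCoord")))
                if not xs:
                    continue
                if not 0 <= z < shape[2]:
                    raise AnnotationError(
                        f"{path.name}: roi slice {z} outside volume")
                rr, cc = fill_polygon(np.array(xs), np.array(ys),
                                      shape=shape[:2])
                mask[rr, cc, z] = 1
            if mask.sum() == 0:
                continue  # readers without a contour are excluded
            center = tuple(int(round(c))
                           for c in np.argwhere(mask).mean(axis=0))
            out.append(ReaderAnnotation(
                reader_id=reader, nodule_key=key, scan_id=scan_id,
                center=center, mask=mask, malignancy=int(mal_txt),
                semantic_scores=scores).validate())
    return out


def read_manifest(path: str | Path) -> dict:
    """Load a dataset manifest (scans, annotations, labels, split)."""
    return json.loads(Path(path).read_text())
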