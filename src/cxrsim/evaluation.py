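"""Lesion-localization scoring: mark matching, FROC and wAFROC analysis.

Detection output is a list of marks (case, x, y, confidence).  A mark is a
lesion localization (LL) when its center lies within a matching radius
(default: strictly below 30 output pixels) of a ground-truth lesion center
of mass; all other marks are non-lesion localizations (NL).  From the
matched ratings the module computes:

* the FROC curve — lesion localization fraction LLF(z) = TP(z) / n_lesions
  against NLF(z) = FP marks(z) / n_cases;
* the weighted AFROC curve — wLLF(z), the lesion-weight-weighted LLF over
  nodule-containing cases (per-case weights are equal and sum to one),
  against FPF(z), the fraction of nodule-free cases whose highest-rated NL
  is at or above z;
* the wAFROC figure of merit, defined as the weighted two-sample statistic

      FOM = (1 / (K_N * K_F)) * sum_k' sum_k sum_l W_kl * psi(FP_k', z_kl)

  with psi(a, b) = 1 if b > a, 0.5 if b == a, 0 if b < a, and unmarked
  lesions / mark-free normal cases entering as -infinity.  This equals the
  trapezoidal area under the empirical wAFROC curve extended to (1, 1).
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ValidationError

UNMARKED = -math.inf

DEFAULT_MATCH_RADIUS_PX = 30.0


@dataclass
class Mark:
    """One detection mark in output-pixel coordinates with a confidence score."""

    case_id: str
    x: float
    y: float
    score: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValidationError("mark score must be finite")


@dataclass
class MatchedRatings:
    """Marks classified against ground truth, ready for FROC/wAFROC analysis.

    ``lesion_ratings[(case, lesion)]`` is the matched mark's score or -inf;
    ``nl_scores[case]`` the false-positive scores of every case;
    ``lesion_weights`` the per-lesion weights (equal within a case, summing
    to one); ``healthy_cases`` the nodule-free case ids.
    """

    lesion_ratings: dict = field(default_factory=dict)
    lesion_weights: dict = field(default_factory=dict)
    nl_scores: dict = field(default_factory=dict)
    healthy_cases: list = field(default_factory=list)
    diseased_cases: list = field(default_factory=list)

    @property
    def K_N(self) -> int:
        return len(self.diseased_cases)

    @property
    def K_F(self) -> int:
        return len(self.healthy_cases)

    @property
    def n_lesions(self) -> int:
        return len(self.lesion_ratings)

    @property
    def n_cases(self) -> int:
        return self.K_N + self.K_F

    def fp_per_healthy_case(self) -> dict:
        """Highest NL score of each nodule-free case (-inf when mark-free)."""
        return {
            k: (max(self.nl_scores.get(k, [])) if self.nl_scores.get(k) else UNMARKED)
            for k in self.healthy_cases
        }

    def validate(self) -> None:
        sums: dict = {}
        for (case, _lesion), w in self.lesion_weights.items():
            sums[case] = sums.get(case, 0.0) + w
        for case, s in sums.items():
            if abs(s - 1.0) > 1e-6:
                raise ValidationError(f"lesion weights of case {case!r} sum to {s}, not 1")


@dataclass
class FROCCurve:
    """FROC operating points at descending distinct score thresholds."""

    thresholds: np.ndarray
    llf: np.ndarray
    nlf: np.ndarray


@dataclass
class WAFROCResult:
    """wAFROC operating points and the area figure of merit."""

    thresholds: np.ndarray
    fpf: np.ndarray
    wllf: np.ndarray
    fom: float


def lesion_weights(n_lesions: int) -> list[float]:
    """Equal per-case lesion weights 1/L summing to one."""
    if n_lesions < 1:
        raise ValidationError("n_lesions must be >= 1")
    return [1.0 / n_lesions] * n_lesions


def _lesions_frame(manifest) -> tuple[pd.DataFrame, list, list]:
    """Accept a StudyManifest or a lesions DataFrame; return lesions + case split."""
    if hasattr(manifest, "lesions"):
        lesions = manifest.lesions
        cases = manifest.cases
        healthy = list(cases.loc[cases["n_lesions"] == 0, "case_id"].astype(str))
        diseased = list(cases.loc[cases["n_lesions"] > 0, "case_id"].astype(str))
    else:
        lesions = manifest
        healthy = []
        diseased = list(pd.unique(lesions["case_id"].astype(str)))
    return lesions, healthy, diseased


def match_marks(
    marks,
    manifest,
    radius_px: float = DEFAULT_MATCH_RADIUS_PX,
    score_threshold: float | None = None,
    inclusive_radius: bool = False,
) -> MatchedRatings:
    """Classify marks as lesion localizations or false positives.

    Candidate (mark, lesion) pairs whose center-of-mass distance is strictly
    below ``radius_px`` (or <= when ``inclusive_radius``) are matched
    greedily one-to-one in order of descending mark score, ties broken by
    smaller distance then lesion id.  Unmatched marks become false
    positives; unmatched lesions stay unmarked.  Marks below
    ``score_threshold`` (when given) are discarded first.
    """
    lesions, healthy, diseased = _lesions_frame(manifest)
    known_cases = set(healthy) | set(diseased)

    ratings = MatchedRatings(healthy_cases=healthy, diseased_cases=diseased)
    by_case: dict = {}
    for _, row in lesions.iterrows():
        case, lid = str(row["case_id"]), int(row["lesion_id"])
        ratings.lesion_ratings[(case, lid)] = UNMARKED
        w = row["weight"] if "weight" in row and not pd.isna(row["weight"]) else None
        by_case.setdefault(case, []).append((lid, float(row["com_x"]), float(row["com_y"])))
        if w is not None:
            ratings.lesion_weights[(case, lid)] = float(w)
    for case, items in by_case.items():
        if not any((case, lid) in ratings.lesion_weights for lid, _, _ in items):
            for lid, _, _ in items:
                ratings.lesion_weights[(case, lid)] = 1.0 / len(items)
    ratings.validate()
    for case in known_cases:
        ratings.nl_scores.setdefault(case, [])

    seen = set()
    deduped = []
    for m in marks:
        if str(m.case_id) not in known_cases:
            raise ValidationError(f"mark references unknown case {m.case_id!r}")
        if score_threshold is not None and m.score < score_threshold:
            continue
        key = (str(m.case_id), float(m.x), float(m.y), float(m.score))
        if key in seen:
            warnings.warn(f"duplicate mark {key} collapsed")
            continue
        seen.add(key)
        deduped.append(m)

    candidates = []
    for mi, m in enumerate(deduped):
        for lid, cx, cy in by_case.get(str(m.case_id), []):
            dist = math.hypot(m.x - cx, m.y - cy)
            hit = dist <= radius_px if inclusive_radius else dist < radius_px
            if hit:
                candidates.append((-m.score, dist, lid, mi, str(m.case_id)))
    candidates.sort()
    matched_marks: set = set()
    matched_lesions: set = set()
    for neg_score, _dist, lid, mi, case in candidates:
        if mi in matched_marks or (case, lid) in matched_lesions:
            continue
        matched_marks.add(mi)
        matched_lesions.add((case, lid))
        ratings.lesion_ratings[(case, lid)] = -neg_score
    for mi, m in enumerate(deduped):
        if mi not in matched_marks:
            ratings.nl_scores[str(m.case_id)].append(float(m.score))
    return ratings


def _all_scores(ratings: MatchedRatings) -> np.ndarray:
    scores = [s for s in ratings.lesion_ratings.values() if np.isfinite(s)]
    for v in ratings.nl_scores.values():
        scores.extend(v)
    return np.unique(np.asarray(scores, dtype=float))[::-1]


def compute_froc(ratings: MatchedRatings) -> FROCCurve:
    """FROC curve: LLF and NLF at every distinct observed score."""
    if ratings.n_lesions == 0:
        raise ValidationError("no lesions to score")
    zetas = _all_scores(ratings)
    if zetas.size == 0:
        return FROCCurve(np.array([np.inf]), np.array([0.0]), np.array([0.0]))
    z = np.asarray([s for s in ratings.lesion_ratings.values()], dtype=float)
    fp = np.asarray(
        [s for v in ratings.nl_scores.values() for s in v], dtype=float
    )
    llf = np.array([(z >= zeta).mean() for zeta in zetas])
    n_cases = max(ratings.n_cases, 1)
    nlf = np.array([(fp >= zeta).sum() / n_cases for zeta in zetas])
    return FROCCurve(zetas, llf, nlf)


def _psi(a: float, b: float) -> float:
    if b > a:
        return 1.0
    if b == a:
        return 0.5
    return 0.0


def compute_wafroc(ratings: MatchedRatings) -> WAFROCResult:
    """wAFROC curve and figure of merit.

    The FOM is computed from the psi kernel over all (normal case, lesion)
    pairs; the curve is evaluated at every distinct observed score.  FPF
    uses nodule-free cases only; false positives on diseased cases affect
    NLF but not FPF.
    """
    if ratings.K_N < 1:
        raise ValidationError("wAFROC requires at least one nodule-containing case")
    if ratings.K_F < 1:
        raise ValidationError(
            "wAFROC requires nodule-free cases; none present in the manifest"
        )
    fp_k = ratings.fp_per_healthy_case()
    fom = 0.0
    for fp in fp_k.values():
        for (case, lid), z in ratings.lesion_ratings.items():
            fom += ratings.lesion_weights[(case, lid)] * _psi(fp, z)
    fom /= ratings.K_N * ratings.K_F

    zetas = _all_scores(ratings)
    fpf, wllf = [], []
    fp_vals = np.asarray(list(fp_k.values()), dtype=float)
    for zeta in zetas:
        fpf.append(float((fp_vals >= zeta).mean()))
        acc = 0.0
        for (case, lid), z in ratings.lesion_ratings.items():
            if z >= zeta:
                acc += ratings.lesion_weights[(case, lid)]
        wllf.append(acc / ratings.K_N)
    return WAFROCResult(zetas, np.asarray(fpf), np.asarray(wllf), float(fom))


def wafroc_curve_area(result: WAFROCResult) -> float:
    """Trapezoidal area under the wAFROC curve extended from (0,0) to (1,1).

    Cross-check for the psi-kernel FOM; the two agree exactly.
    """
    x = np.concatenate([[0.0], result.fpf, [1.0]])
    y = np.concatenate([[0.0], result.wllf, [1.0]])
    return float(np.trapezoid(y, x))


def wllf_at(result: WAFROCResult, fpf: float) -> float:
    """Interpolate wLLF at a requested FPF operating point.

    Linear interpolation between adjacent curve points, using (0,0) and the
    (1,1) extension as end anchors; at an FPF reached by several thresholds
    the highest wLLF applies.
    """
    if not 0.0 <= fpf <= 1.0:
        raise ValidationError("fpf must lie in [0, 1]")
    x = np.concatenate([[0.0], result.fpf, [1.0]])
    y = np.concatenate([[0.0], result.wllf, [1.0]])
    best: dict = {}
    for xi, yi in zip(x, y):
        best[xi] = max(best.get(xi, 0.0), yi)
    xs = np.array(sorted(best))
    ys = np.array([best[xi] for xi in xs])
    return float(np.interp(fpf, xs, ys))


def summarize_counts(
    ratings: MatchedRatings, zeta: float, strict: bool = False
) -> tuple[int, int, int]:
    """(TP, FP, FN) at a threshold; ``strict`` uses > zeta instead of >= zeta."""
    def passes(s: float) -> bool:
        return s > zeta if strict else s >= zeta

    tp = sum(1 for z in ratings.lesion_ratings.values() if np.isfinite(z) and passes(z))
    fp = sum(1 for v in ratings.nl_scores.values() for s in v if passes(s))
    fn = ratings.n_lesions - tp
    return tp, fp, fn


def combine_detections(boxes, seg_marks) -> list[Mark]:
    """Keep a detector's boxes confirmed by a segmentation mark inside them.

    ``boxes`` are ``(case_id, (x0, y0, x1, y1), score)`` with min < max
    corners; a box is retained iff some segmentation mark of the same case
    lies inside it (edges inclusive), and emits a Mark at the box center
    with the box's score.
    """
    out = []
    for case_id, corners, score in boxes:
        x0, y0, x1, y1 = (float(c) for c in corners)
        if not (x0 < x1 and y0 < y1):
            raise ValidationError(f"degenerate box {corners} in case {case_id!r}")
        for m in seg_marks:
            if str(m.case_id) == str(case_id) and x0 <= m.x <= x1 and y0 <= m.y <= y1:
                out.append(Mark(str(case_id), (x0 + x1) / 2, (y0 + y1) / 2, float(score)))
                break
    return out


def marks_from_segmentation(mask: np.ndarray, score_image=None, case_id: str = "") -> list[Mark]:
    """One mark per 8-connected component of a binary segmentation.

    The mark sits at the component's center of mass; its score is the
    maximum of ``score_image`` over the component, or 1.0 when absent.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValidationError("segmentation mask must be 2D")
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    out = []
    for lab in range(1, n + 1):
        comp = labels == lab
        cy, cx = ndimage.center_of_mass(comp)
        score = 1.0 if score_image is None else float(np.asarray(score_image)[comp].max())
        out.append(Mark(case_id, float(cx), float(cy), score))
    return out


# ---------------------------------------------------------------------------
# Rating tables (Truth / NL / LL three-table layout)

def write_rating_table(
    path, truth: pd.DataFrame, nl: pd.DataFrame, ll: pd.DataFrame
) -> None:
    """Write a Truth/NL/LL rating table as xlsx (sheets) or CSV directory.

    Truth: CaseID, LesionID (0 for nodule-free cases), Weight.
    NL: ReaderID, ModalityID, CaseID, NL_Rating.
    LL: ReaderID, ModalityID, CaseID, LesionID, LL_Rating.
    """
    path = str(path)
    if path.endswith(".xlsx"):
        with pd.ExcelWriter(path, engine="openpyxl") as writer:
            truth.to_excel(writer, sheet_name="TRUTH", index=False)
            nl.to_excel(writer, sheet_name="NL", index=False)
            ll.to_excel(writer, sheet_name="LL", index=False)
    else:
        os.makedirs(path, exist_ok=True)
        truth.to_csv(os.path.join(path, "Truth.csv"), index=False)
        nl.to_csv(os.path.join(path, "NL.csv"), index=False)
        ll.to_csv(os.path.join(path, "LL.csv"), index=False)


def _read_tables(path: str):
    if path.endswith(".xlsx"):
        sheets = pd.read_excel(path, sheet_name=None, engine="openpyxl")
        keyed = {k.strip().upper(): v for k, v in sheets.items()}
        try:
            return keyed["TRUTH"], keyed["NL"], keyed["LL"]
        except KeyError as exc:
            raise ValidationError(f"{path}: missing sheet {exc}") from exc
    truth = pd.read_csv(os.path.join(path, "Truth.csv"))
    nl = pd.read_csv(os.path.join(path, "NL.csv"))
    ll = pd.read_csv(os.path.join(path, "LL.csv"))
    return truth, nl, ll


def load_rating_table(path) -> dict:
    """Load a Truth/NL/LL rating table into MatchedRatings per reader/modality.

    Returns ``{(modality_id, reader_id): MatchedRatings}``.  Lesion weights
    must sum to one per nodule-containing case (within 1e-6) and every LL
    row must reference a lesion present in Truth.
    """
    truth, nl, ll = _read_tables(str(path))
    truth = truth.rename(columns=lambda c: str(c).strip())
    healthy, diseased = [], []
    weights: dict = {}
    for case, grp in truth.groupby("CaseID"):
        case = str(case)
        lids = [int(v) for v in grp["LesionID"]]
        if set(lids) == {0}:
            healthy.append(case)
            continue
        diseased.append(case)
        total = 0.0
        for _, row in grp.iterrows():
            lid = int(row["LesionID"])
            if lid == 0:
                continue
            w = float(row["Weight"])
            weights[(case, lid)] = w
            total += w
        if abs(total - 1.0) > 1e-6:
            raise ValidationError(f"case {case}: lesion weights sum to {total}, not 1")

    pairs = sorted(
        set(zip(nl["ModalityID"].astype(str), nl["ReaderID"].astype(str)))
        | set(zip(ll["ModalityID"].astype(str), ll["ReaderID"].astype(str)))
    )
    out = {}
    for mod, reader in pairs:
        r = MatchedRatings(
            healthy_cases=list(healthy),
            diseased_cases=list(diseased),
            lesion_weights=dict(weights),
        )
        for key in weights:
            r.lesion_ratings[key] = UNMARKED
        for case in healthy + diseased:
            r.nl_scores[case] = []
        sel = ll[(ll["ModalityID"].astype(str) == mod) & (ll["ReaderID"].astype(str) == reader)]
        for _, row in sel.iterrows():
            key = (str(row["CaseID"]), int(row["LesionID"]))
            if key not in r.lesion_ratings:
                raise ValidationError(f"LL row references unknown lesion {key}")
            r.lesion_ratings[key] = float(row["LL_Rating"])
        sel = nl[(nl["ModalityID"].astype(str) == mod) & (nl["ReaderID"].astype(str) == reader)]
        for _, row in sel.iterrows():
            case = str(row["CaseID"])
            if case not in r.nl_scores:
                raise ValidationError(f"NL row references unknown case {case!r}")
            r.nl_scores[case].append(float(row["NL_Rating"]))
        out[(mod, reader)] = r
    return out


def curves_to_frame(froc: FROCCurve, wafroc: WAFROCResult) -> pd.DataFrame:
    """Tabulate FROC and wAFROC operating points on a shared threshold grid."""
    df = pd.DataFrame(
        dict(zeta=froc.thresholds, LLF=froc.llf, NLF=froc.nlf)
    )
    wa = pd.DataFrame(dict(zeta=wafroc.thresholds, FPF=wafroc.fpf, wLLF=wafroc.wllf))
    return df.merge(wa, on="zeta", how="outer").sort_values("zeta", ascending=False)


def plot_curves(froc: FROCCurve, wafroc: WAFROCResult, path) -> None:
    """Plot FROC and wAFROC curves side by side to a PNG/SVG file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.plot(froc.nlf, froc.llf, marker="o", ms=3)
    ax1.set_xlabel("NLF (non-lesion localizations per case)")
    ax1.set_ylabel("LLF")
    ax1.set_title("FROC")
    x = np.concatenate([[0.0], wafroc.fpf, [1.0]])
    y = np.concatenate([[0.0], wafroc.wllf, [1.0]])
    ax2.plot(x, y, marker="o", ms=3)
    ax2.set_xlabel("FPF (nodule-free cases)")
    ax2.set_ylabel("wLLF")
    ax2.set_title(f"wAFROC (FOM = {wafroc.fom:.3f})")
    ax2.set_xlim(0, 1)
    ax2.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(str(path), dpi=120)
    plt.close(fig)
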