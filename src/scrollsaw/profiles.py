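"""Per-paralog sequence profiles and margin-rule classification.

Each ancestral paralog is summarised as a position-specific log-odds profile
built from the sub-alignment of its retained representatives. Query sequences
are scored by best local alignment (affine gaps, free ends, score floor 0)
against every profile; a query is assigned to the best-scoring paralog only
if the bit-score margin over the runner-up reaches a threshold (default 20
bits). Tree evidence, when available, takes precedence over the profile rule.

The scorer is a position-specific Smith–Waterman, not a plan7 HMM: absolute
bit scores are not comparable with HMMER's, but the margin decision rule is
the same and the threshold is configurable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._wag import WAG_PI
from .evomodel import AA_ORDER
from .treeops import assign_by_supported_clade

__all__ = [
    "ProfileModel",
    "ScoreReport",
    "AnnotationDecision",
    "build_profile",
    "profile_score",
    "score_report",
    "classify_by_margin",
    "annotate_sequence",
    "save_profiles",
    "load_profiles",
]

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}
DEFAULT_MARGIN_BITS = 20.0


@dataclass
class ProfileModel:
    """Position-specific log-odds profile for one paralog.

    ``match_scores`` is (n_match_columns, 20) in bits against ``background``;
    gap costs are affine (open + extend per additional gapped position).
    """

    name: str
    match_scores: np.ndarray
    background: np.ndarray
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self):
        self.match_scores = np.asarray(self.match_scores, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.match_scores.ndim != 2 or self.match_scores.shape[1] != 20:
            raise ValueError("match_scores must be (n_columns, 20)")
        if self.match_scores.shape[0] < 1:
            raise ValueError("profile needs at least one match column")
        if not np.all(np.isfinite(self.match_scores)):
            raise ValueError("non-finite emission scores")

    @property
    def n_columns(self) -> int:
        return self.match_scores.shape[0]


@dataclass
class ScoreReport:
    """Best local-alignment bit scores of one query against a profile set."""

    seq_id: str
    scores: dict[str, float]

    @property
    def best(self) -> str:
        return max(self.scores, key=lambda k: (self.scores[k], k))

    @property
    def second(self) -> str | None:
        if len(self.scores) < 2:
            return None
        ordered = sorted(self.scores, key=lambda k: (-self.scores[k], k))
        return ordered[1]

    @property
    def margin(self) -> float | None:
        if len(self.scores) < 2:
            return None
        return self.scores[self.best] - self.scores[self.second]


@dataclass
class AnnotationDecision:
    label: str
    method: str  # "tree" | "profile" | "both_fail"
    evidence: dict = field(default_factory=dict)


def build_profile(
    sub_alignment,
    name: str,
    background: np.ndarray | None = None,
    *,
    min_occupancy: float = 0.5,
    pseudocount_mass: float = 1.0,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> ProfileModel:
    """Build a profile from the sub-alignment of one paralog's sequences.

    Match columns are those with residue occupancy >= ``min_occupancy``.
    Emissions are log2 odds of background-weighted pseudocounted frequencies:
    ``log2(((count + 0.5*bg*m) / (total + 0.5*m)) / bg)`` with pseudocount
    mass ``m`` split across residues by the background.
    """
    rows = list(sub_alignment.rows)
    if len(rows) < 2:
        raise ValueError("profile construction needs >= 2 rows")
    bg = np.asarray(background if background is not None else WAG_PI, dtype=float)
    bg = bg / bg.sum()
    n_cols = sub_alignment.n_columns
    mat = np.array([[_AA_INDEX.get(c, -1) for c in r.residues] for r in rows])
    gaps = np.array([[c == "-" for c in r.residues] for r in rows])
    occupancy = 1.0 - gaps.mean(axis=0)
    cols = []
    for j in range(n_cols):
        if occupancy[j] < min_occupancy:
            continue
        col = mat[:, j]
        counts = np.bincount(col[col >= 0], minlength=20).astype(float)
        total = counts.sum()
        freq = (counts + 0.5 * bg * pseudocount_mass) / (total + 0.5 * pseudocount_mass)
        cols.append(np.log2(freq / bg))
    if not cols:
        raise ValueError(f"no columns reach occupancy {min_occupancy} in profile {name!r}")
    return ProfileModel(name=name, match_scores=np.array(cols), background=bg,
                        gap_open=gap_open, gap_extend=gap_extend)


def profile_score(profile: ProfileModel, seq: str) -> float:
    """Best local alignment score (bits) of a sequence against a profile.

    Smith–Waterman over profile columns × sequence positions with affine gap
    costs, free start/end on both sides, and a score floor of 0.
    """
    if not seq:
        raise ValueError("empty sequence")
    enc = np.array([_AA_INDEX.get(c, -1) for c in seq.upper().replace("-", "")])
    m = len(enc)
    S = profile.match_scores
    # ambiguous residues (X) score 0 = background expectation
    emis = np.where(enc[None, :] >= 0, S[:, np.clip(enc, 0, 19)], 0.0)
    go, ge = profile.gap_open, profile.gap_extend
    idx = np.arange(m)
    H_prev = np.zeros(m + 1)
    F = np.full(m + 1, -np.inf)
    best = 0.0
    for i in range(profile.n_columns):
        F = np.maximum(H_prev - go, F - ge)
        diag = H_prev[:-1] + emis[i]
        H0 = np.maximum.reduce([diag, F[1:], np.zeros(m)])
        # gaps along the sequence axis from final H entries to the left;
        # chains E->H->E are never optimal when gap_open >= gap_extend,
        # so one pass over the candidate row is exact
        G = np.maximum.accumulate(H0 + ge * idx)
        E = np.concatenate([[-np.inf], G[:-1]]) - go + ge - ge * idx
        H = np.maximum(H0, np.maximum(E, 0.0))
        best = max(best, float(H.max()))
        H_prev = np.concatenate([[0.0], H])
    return best


def score_report(profiles: list[ProfileModel], seq: str, seq_id: str = "") -> ScoreReport:
    return ScoreReport(seq_id=seq_id,
                       scores={p.name: profile_score(p, seq) for p in profiles})


def classify_by_margin(report: ScoreReport,
                       margin_threshold: float = DEFAULT_MARGIN_BITS) -> str | None:
    """Best-hit label iff the margin over the runner-up reaches the threshold
    ("equal to or higher" passes); otherwise unassigned (None)."""
    if len(report.scores) < 2:
        warnings.warn("margin undefined with fewer than 2 profiles; unassigned")
        return None
    if report.margin >= margin_threshold:
        return report.best
    return None


def annotate_sequence(
    seq,
    profiles: list[ProfileModel],
    *,
    tree=None,
    refs: dict[str, str] | None = None,
    sh_min: float = 80.0,
    ufboot_min: float = 95.0,
    composites: dict[frozenset, str] | None = None,
    margin_threshold: float = DEFAULT_MARGIN_BITS,
) -> AnnotationDecision:
    """Combined annotation decision for one sequence.

    The tree rule (smallest dual-support clade with references) is tried
    first when a tree is supplied; the profile margin rule is the fallback;
    failing both, the sequence is "unclassified".
    """
    if not profiles:
        raise ValueError("no profiles supplied")
    seq_id = getattr(seq, "id", "")
    residues = getattr(seq, "ungapped", None) or (seq if isinstance(seq, str) else seq.residues)
    if tree is not None and refs:
        label = assign_by_supported_clade(tree, seq_id, refs, sh_min=sh_min,
                                          ufboot_min=ufboot_min, composites=composites)
        if label is not None:
            return AnnotationDecision(label=label, method="tree",
                                      evidence={"sh_min": sh_min, "ufboot_min": ufboot_min})
    report = score_report(profiles, residues, seq_id=seq_id)
    if len(report.scores) >= 2 and report.margin >= margin_threshold:
        return AnnotationDecision(
            label=report.best, method="profile",
            evidence={"best_score": report.scores[report.best],
                      "second_score": report.scores[report.second],
                      "margin": report.margin},
        )
    return AnnotationDecision(label="unclassified", method="both_fail",
                              evidence={"scores": report.scores})


def save_profiles(profiles: list[ProfileModel], dest) -> None:
    """Serialise a profile database as JSON lines."""
    handle, close = (open(dest, "w"), True) if isinstance(dest, (str, Path)) else (dest, False)
    try:
        for p in profiles:
            handle.write(json.dumps({
                "name": p.name,
                "match_scores": p.match_scores.round(6).tolist(),
                "background": p.background.tolist(),
                "gap_open": p.gap_open,
                "gap_extend": p.gap_extend,
            }) + "\n")
    finally:
        if close:
            handle.close()


def load_profiles(source) -> list[ProfileModel]:
    handle, close = (open(source), True) if isinstance(source, (str, Path)) else (source, False)
    try:
        out = []
        for line in handle:
            if line.strip():
                d = json.loads(line)
                out.append(ProfileModel(
                    name=d["name"], match_scores=np.array(d["match_scores"]),
                    background=np.array(d["background"]),
                    gap_open=d["gap_open"], gap_extend=d["gap_extend"],
                ))
        return out
    finally:
        if close:
            handle.close()
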