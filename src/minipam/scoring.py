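"""Positional-feature on-target activity scoring (CRISPRscan-style).

The model is a linear combination of indicator features — 1-mers and 2-mers
at fixed positions of the 35-mer context — plus an intercept, affinely
rescaled to 0-100. For relaxed-PAM variants the context is scored *as if*
the PAM were NGG: PAM positions 2-3 of the context (positions 28-29,
1-based) are substituted with GG before feature matching, and the leading
N-position base is retained. Scores above the activity threshold (default
66, strict) flag a target as predicted highly efficient.

Model coefficients are data, not code: they are loaded from a TSV
(``position<TAB>feature<TAB>weight`` rows, plus ``intercept``/``raw_min``/
``raw_max`` footer rows) so the published coefficient set can be transcribed
without touching the implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .pam_engine import TargetSite

CONTEXT_LENGTH = 35
#: 1-based context positions of the 2nd and 3rd PAM base (the "GG" of NGG)
PAM_GG_POSITIONS = (28, 29)
DEFAULT_THRESHOLD = 66.0

_SCALE_KEYS = ("intercept", "raw_min", "raw_max")


@dataclass
class ScoreModel:
    """Positional weights + intercept + affine 0-100 scaling."""

    entries: list[tuple[int, str, float]]  # (1-based position, feature, weight)
    intercept: float
    raw_min: float
    raw_max: float
    model_id: str = "unnamed"

    def __post_init__(self):
        seen = set()
        for pos, feat, _w in self.entries:
            if not feat or set(feat) - set("ACGT") or len(feat) > 2:
                raise ValueError(f"invalid feature {feat!r} (must be 1- or 2-mer over ACGT)")
            if not 1 <= pos <= CONTEXT_LENGTH - (len(feat) - 1):
                raise ValueError(f"position {pos} out of range for feature {feat!r}")
            if (pos, feat) in seen:
                raise ValueError(f"duplicate model entry at position {pos}, feature {feat!r}")
            seen.add((pos, feat))
        if not self.raw_min < self.raw_max:
            raise ValueError("raw_min must be < raw_max")


@dataclass(frozen=True)
class ScoredTarget:
    site: TargetSite
    score: float | None
    high_efficiency_predicted: bool = False
    threshold: float = DEFAULT_THRESHOLD


def load_score_model(path: str | Path) -> ScoreModel:
    entries: list[tuple[int, str, float]] = []
    scale: dict[str, float] = {}
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:  # skip header
        if not line.strip() or line.startswith("#"):
            continue
        key, feat, value = line.split("\t")
        if key in _SCALE_KEYS:
            scale[key] = float(value)
        else:
            entries.append((int(key), feat, float(value)))
    missing = [k for k in _SCALE_KEYS if k not in scale]
    if missing:
        raise ValueError(f"model file missing scale keys: {missing}")
    return ScoreModel(
        entries=entries,
        intercept=scale["intercept"],
        raw_min=scale["raw_min"],
        raw_max=scale["raw_max"],
        model_id=Path(path).stem,
    )


def save_score_model(model: ScoreModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tfeature\tweight\n")
        for pos, feat, w in model.entries:
            fh.write(f"{pos}\t{feat}\t{w!r}\n")
        fh.write(f"intercept\t.\t{model.intercept!r}\n")
        fh.write(f"raw_min\t.\t{model.raw_min!r}\n")
        fh.write(f"raw_max\t.\t{model.raw_max!r}\n")


def canonicalize_pam(context35: str) -> str:
    """Substitute PAM positions 2-3 with GG; the leading PAM base (the N of
    NGG, context position 27) is retained."""
    if len(context35) != CONTEXT_LENGTH:
        raise ValueError(f"context must be {CONTEXT_LENGTH} nt, got {len(context35)}")
    chars = list(context35)
    for pos in PAM_GG_POSITIONS:
        chars[pos - 1] = "G"
    return "".join(chars)


def score_context(model: ScoreModel, context35: str) -> float:
    """Score one 35-mer: canonicalize the PAM, sum matched positional
    weights, then affinely map to [0, 100] with clamping."""
    ctx = canonicalize_pam(context35)
    raw = model.intercept
    for pos, feat, w in model.entries:
        if ctx[pos - 1 : pos - 1 + len(feat)] == feat:
            raw += w
    scaled = 100.0 * (raw - model.raw_min) / (model.raw_max - model.raw_min)
    return min(100.0, max(0.0, scaled))


def score_target(
    model: ScoreModel, site: TargetSite, threshold: float = DEFAULT_THRESHOLD
) -> ScoredTarget:
    """Score a site; edge-truncated sites (no 35-mer context) come back
    unscored rather than raising."""
    if site.context35 is None:
        return ScoredTarget(site=site, score=None, threshold=threshold)
    score = score_context(model, site.context35)
    return ScoredTarget(
        site=site,
        score=score,
        high_efficiency_predicted=classify_high_score(score, threshold),
        threshold=threshold,
    )


def score_sites(
    model: ScoreModel, sites: Iterable[TargetSite], threshold: float = DEFAULT_THRESHOLD
) -> list[ScoredTarget]:
    return [score_target(model, s, threshold) for s in sites]


def classify_high_score(score: float, threshold: float = DEFAULT_THRESHOLD) -> bool:
    """Strictly above the threshold (>66 vs <=66 grouping)."""
    return score > threshold
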