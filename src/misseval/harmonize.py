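"""Harmonization of raw predictor outputs to binary pathogenic/benign calls.

The four predictors emit heterogeneous outputs: Align-GVGD a seven-grade
class C0..C65, SIFT a score in [0, 1] (or a label), MutationTaster2 and
PolyPhen-2 categorical labels.  The cut-offs here follow routine diagnostic
usage: Align-GVGD pathogenic at C>=35, SIFT pathogenic strictly below 0.05,
PolyPhen-2 pathogenic for possibly/probably damaging, MutationTaster2
pathogenic for "disease causing".

Calls are the strings ``"P"`` / ``"B"``; a missing raw value harmonizes to
``None`` and the variant is dropped from that tool's confusion matrix
(pairwise-complete evaluation).  Each harmonizer is idempotent on
already-binary calls and rejects anything outside its vocabulary.
"""

from __future__ import annotations

import math
import re

__all__ = [
    "TOOLS",
    "PATHOGENIC",
    "BENIGN",
    "HarmonizationError",
    "harmonize_align_gvgd",
    "harmonize_sift",
    "harmonize_mt2",
    "harmonize_polyphen2",
    "harmonize_record",
    "RAW_COLUMNS",
]

PATHOGENIC = "P"
BENIGN = "B"

#: Canonical tool order used throughout (matrices, ensembles, reports).
TOOLS = ("align_gvgd", "sift", "mutation_taster2", "polyphen2")

#: Raw TSV columns consumed per tool (SIFT accepts a score or a label).
RAW_COLUMNS = {
    "align_gvgd": ("agvgd_class",),
    "sift": ("sift_score", "sift_label"),
    "mutation_taster2": ("mt2_label",),
    "polyphen2": ("pph2_label",),
}

_AGVGD_GRADES = {f"c{g}": g for g in (0, 15, 25, 35, 45, 55, 65)}
_WS = re.compile(r"[\s_]+")


class HarmonizationError(ValueError):
    """Raw predictor output outside the tool's declared vocabulary."""


def _norm(label: str) -> str:
    return _WS.sub(" ", label.strip().lower())


def _passthrough(raw: object) -> str | None:
    if isinstance(raw, str) and raw in (PATHOGENIC, BENIGN):
        return raw
    return None


def harmonize_align_gvgd(grade: object) -> str:
    """Binary call from an Align-GVGD grade: pathogenic iff C >= 35."""
    if (call := _passthrough(grade)) is not None:
        return call
    if not isinstance(grade, str) or _norm(grade) not in _AGVGD_GRADES:
        raise HarmonizationError(
            f"unknown Align-GVGD grade {grade!r}; expected one of "
            + ", ".join(sorted(g.upper() for g in _AGVGD_GRADES))
        )
    return PATHOGENIC if _AGVGD_GRADES[_norm(grade)] >= 35 else BENIGN


def harmonize_sift(raw: object) -> str:
    """Binary call from a SIFT score or label.

    Pathogenic iff score < 0.05 (a score of exactly 0.05 is tolerated) or
    the label is AFFECT PROTEIN FUNCTION.
    """
    if (call := _passthrough(raw)) is not None:
        return call
    if isinstance(raw, str):
        label = _norm(raw)
        if label == "affect protein function":
            return PATHOGENIC
        if label == "tolerated":
            return BENIGN
        raise HarmonizationError(
            f"unknown SIFT label {raw!r}; expected AFFECT PROTEIN FUNCTION or TOLERATED"
        )
    score = float(raw)
    if not (0.0 <= score <= 1.0) or not math.isfinite(score):
        raise HarmonizationError(f"SIFT score {score} outside [0, 1]")
    return PATHOGENIC if score < 0.05 else BENIGN


def harmonize_mt2(label: object) -> str:
    """MutationTaster2: pathogenic iff "disease causing"."""
    if (call := _passthrough(label)) is not None:
        return call
    if isinstance(label, str):
        norm = _norm(label)
        if norm == "disease causing":
            return PATHOGENIC
        if norm == "polymorphism":
            return BENIGN
    raise HarmonizationError(
        f"unknown MutationTaster2 label {label!r}; expected "
        "'disease causing' or 'polymorphism'"
    )


def harmonize_polyphen2(label: object) -> str:
    """PolyPhen-2: pathogenic iff possibly or probably damaging."""
    if (call := _passthrough(label)) is not None:
        return call
    if isinstance(label, str):
        norm = _norm(label)
        if norm in ("possibly damaging", "probably damaging"):
            return PATHOGENIC
        if norm == "benign":
            return BENIGN
    raise HarmonizationError(
        f"unknown PolyPhen-2 label {label!r}; expected 'benign', "
        "'possibly damaging' or 'probably damaging'"
    )


_HARMONIZERS = {
    "align_gvgd": harmonize_align_gvgd,
    "sift": harmonize_sift,
    "mutation_taster2": harmonize_mt2,
    "polyphen2": harmonize_polyphen2,
}


def harmonize_tool(tool: str, raw: object) -> str:
    if tool not in _HARMONIZERS:
        raise HarmonizationError(f"unknown tool {tool!r}; expected one of {TOOLS}")
    return _HARMONIZERS[tool](raw)


def harmonize_record(raw_calls: dict[str, object]) -> dict[str, str | None]:
    """Harmonize one variant's raw outputs into per-tool binary calls.

    ``raw_calls`` is keyed by raw column name (``agvgd_class``,
    ``sift_score``, ``sift_label``, ``mt2_label``, ``pph2_label``); a tool
    with no non-missing column yields ``None``.  When both a SIFT score and
    label are present the score wins (it carries more information).
    """
    calls: dict[str, str | None] = {}
    for tool, columns in RAW_COLUMNS.items():
        raw = next(
            (raw_calls[c] for c in columns if raw_calls.get(c) not in (None, "")),
            None,
        )
        calls[tool] = None if raw is None else _HARMONIZERS[tool](raw)
    return calls
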