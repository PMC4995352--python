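"""Effectiveness-claim keyword filter and dual-reviewer relevance merge.

Clinical relevance is a human judgment: this module ingests two reviewers'
independent labels, surfaces disagreements, and requires an explicit
resolution for each before any downstream proportion is computed. The claim
filter is the fixed keyword pre-screen applied to store descriptions before
manual assessment of effectiveness claims.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .errors import PendingConsensusError, StorefluxError

_TOKEN_RE = re.compile(r"[a-z0-9]+")


@dataclass(frozen=True)
class ClaimKeywordSet:
    """The effectiveness-claim vocabulary.

    ``exact_tokens`` match whole tokens only (so "clinically" does NOT match
    "clinical"); ``prefix_tokens`` are the starred, stemmed entries matching
    any token that begins with them ("effective*" catches "effectiveness",
    "evaluate*" catches "evaluated"). Matching is case-insensitive; "RCT"
    matches as a whole token.
    """

    exact_tokens: frozenset = frozenset(
        {
            "clinical",
            "study",
            "studies",
            "proven",
            "proof",
            "tested",
            "guaranteed",
            "evidence",
            "rct",
            "trial",
        }
    )
    prefix_tokens: tuple = ("effective", "evaluate")


DEFAULT_KEYWORDS = ClaimKeywordSet()


def claim_keyword_filter(
    description: str, keywords: ClaimKeywordSet = DEFAULT_KEYWORDS
) -> tuple[bool, list[str]]:
    """Pre-screen a store description for effectiveness-claim keywords.

    Tokenizes on non-alphanumeric boundaries, lowercases, and reports a
    match if any token equals an exact keyword or starts with a prefix
    keyword. Returns the matched keyword entries (prefix entries are
    reported with their trailing ``*``), deduplicated, in keyword order.
    """
    tokens = set(_TOKEN_RE.findall(description.lower()))
    hits = []
    for prefix in keywords.prefix_tokens:
        if any(tok.startswith(prefix) for tok in tokens):
            hits.append(prefix + "*")
    for exact in sorted(keywords.exact_tokens):
        if exact in tokens:
            hits.append(exact)
    return (bool(hits), hits)


@dataclass
class ReviewOutcome:
    """Per-app dual-review result with consensus."""

    app_id: str
    label_reviewer1: bool
    label_reviewer2: bool
    consensus: bool
    disagreement: bool = field(default=False)


def merge_dual_review(
    labels1: Mapping[str, bool],
    labels2: Mapping[str, bool],
    resolutions: Optional[Mapping[str, bool]] = None,
) -> dict[str, ReviewOutcome]:
    """Merge two reviewers' independent relevance labels into consensus.

    Agreement carries directly; every disagreement must have an entry in
    ``resolutions`` (the discussed consensus), otherwise a
    :class:`PendingConsensusError` lists the unresolved apps. Resolutions
    must cover exactly the disagreeing apps.
    """
    resolutions = dict(resolutions or {})
    if set(labels1) != set(labels2):
        only1 = sorted(set(labels1) - set(labels2))
        only2 = sorted(set(labels2) - set(labels1))
        raise StorefluxError(
            f"reviewer label coverage differs (only reviewer 1: {only1}; only reviewer 2: {only2})"
        )
    disagreeing = {a for a in labels1 if labels1[a] != labels2[a]}
    unresolved = sorted(disagreeing - set(resolutions))
    if unresolved:
        raise PendingConsensusError(f"consensus pending for app(s): {unresolved}")
    extra = sorted(set(resolutions) - disagreeing)
    if extra:
        raise StorefluxError(f"resolutions given for non-disagreeing app(s): {extra}")
    out = {}
    for app_id in labels1:
        disagrees = app_id in disagreeing
        out[app_id] = ReviewOutcome(
            app_id=app_id,
            label_reviewer1=bool(labels1[app_id]),
            label_reviewer2=bool(labels2[app_id]),
            consensus=bool(resolutions[app_id]) if disagrees else bool(labels1[app_id]),
            disagreement=disagrees,
        )
    return out


def relevance_proportion(per_platform: list[tuple[int, int]]) -> float:
    """Pooled percentage of relevant apps across platforms, to one decimal.

    Input is a list of (n_relevant, n_total) pairs, one per platform; the
    proportion pools numerators and denominators before rounding.
    """
    total_rel = total = 0
    for n_rel, n_tot in per_platform:
        if n_rel < 0 or n_tot < 0:
            raise StorefluxError("counts must be nonnegative")
        if n_rel > n_tot:
            raise StorefluxError(f"n_relevant {n_rel} exceeds n_total {n_tot}")
        total_rel += n_rel
        total += n_tot
    if total == 0:
        raise StorefluxError("total app count is zero")
    return round(100.0 * total_rel / total, 1)
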