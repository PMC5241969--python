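"""Scoring and admissibility filter for structural template candidates."""

from __future__ import annotations

from .types import TemplateCandidate

ADMISSIBILITY_CUTOFF = 0.40


def match_score(c: TemplateCandidate) -> float:
    """Combined identity-times-coverage match score (range [0, 2])."""
    return c.m


def template_admissible(c: TemplateCandidate, cutoff: float = ADMISSIBILITY_CUTOFF) -> bool:
    """Whether a template is usable for modelling.

    Requires all four of identity and coverage for both chains to be
    strictly above the cutoff.  (The looser reading — any one metric
    above the cutoff — is deliberately not used; see docs.)
    """
    return (
        c.seqid1 > cutoff
        and c.cov1 > cutoff
        and c.seqid2 > cutoff
        and c.cov2 > cutoff
    )


def best_template(candidates) -> TemplateCandidate:
    """Highest match score among admissible candidates."""
    admissible = [c for c in candidates if template_admissible(c)]
    if not admissible:
        raise ValueError("no admissible template candidates")
    return max(admissible, key=match_score)
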