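"""Pluggable disease-name to disease-ID mapping.

A simple exact-match table after whitespace/case normalization; names
that do not map are dropped (with a logged count) rather than raising.
"""

from __future__ import annotations

import logging
import re
from typing import List, Mapping, Sequence

logger = logging.getLogger(__name__)

_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    return _WS.sub(" ", name.strip().casefold())


def map_disease_names(names: Sequence[str], table: Mapping[str, str]) -> List[str]:
    """Map disease names to IDs; unmapped names are dropped.

    The table is keyed by normalized names (lower-cased, collapsed
    whitespace).  Returns the IDs of mapped names in input order.
    """
    normalized_table = {normalize_name(k): v for k, v in table.items()}
    out: List[str] = []
    dropped = 0
    for name in names:
        key = normalize_name(name)
        if key in normalized_table:
            out.append(normalized_table[key])
        else:
            dropped += 1
    if dropped:
        logger.warning("dropped %d of %d unmapped disease names", dropped, len(names))
    return out
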