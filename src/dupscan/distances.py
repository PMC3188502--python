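"""Pairing of binding-site instances within modules.

The pair distance r is measured between the 5'-most genomic start
coordinates on the plus strand (the BED start), with the left site as
member A of the pair.
"""

from __future__ import annotations

from typing import Sequence

from .evolution_model import SitePair, choose_offset
from .seq_io import SiteInstance


def build_site_pairs(
    instances: Sequence[SiteInstance],
    max_distance: int | None = None,
    offset_t: float = 1.0,
) -> list[SitePair]:
    """All within-module site pairs, ordered left-to-right.

    When motif lengths differ, the gapless alignment offset is chosen to
    maximize the common-descent likelihood at evolutionary distance
    ``offset_t``.  ``max_distance`` restricts pairs by start-to-start
    distance.
    """
    by_module: dict[str, list[SiteInstance]] = {}
    for si in instances:
        by_module.setdefault(si.annotation.module_id, []).append(si)
    pairs: list[SitePair] = []
    for sites in by_module.values():
        sites = sorted(sites, key=lambda s: s.annotation.start)
        for i in range(len(sites)):
            for j in range(i + 1, len(sites)):
                r = sites[j].annotation.start - sites[i].annotation.start
                if max_distance is not None and r > max_distance:
                    continue
                pair = SitePair(sites[i], sites[j], distance=r)
                if sites[i].motif.length != sites[j].motif.length:
                    pair.offset = choose_offset(pair, offset_t)
                pairs.append(pair)
    return pairs
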