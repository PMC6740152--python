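"""End-to-end survey of one genome for a SIDE/LINE family pair.

Chains the stages the way a full study would: search each family consensus
against the genome, discard fragments shorter than the disambiguation
threshold (the shared 5'/3' ends mean short fragments cannot be attributed
to either family), defragment, estimate per-copy Jukes-Cantor divergence and
bin the activity-through-age landscape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .align import GenomeIndex, ScoringScheme, search_genome
from .io import DnaRecord, PipelineConfig
from .landscape import (
    LandscapeTable,
    MergedCopy,
    activity_landscape,
    copy_divergence,
    filter_fragments,
    genome_coverage,
    merge_adjacent,
)

logger = logging.getLogger("sidescan")


@dataclass
class FamilySurvey:
    """One family's annotated copies in one genome."""

    consensus: DnaRecord
    copies: list[MergedCopy]
    landscape: LandscapeTable
    coverage: float

    @property
    def copy_number(self) -> int:
        return len(self.copies)


def survey_family(
    consensus: DnaRecord,
    genome: list[DnaRecord],
    config: PipelineConfig | None = None,
    scheme: ScoringScheme | None = None,
    indexes: dict[str, GenomeIndex] | None = None,
) -> FamilySurvey:
    """Search, filter, defragment and age one family in one genome."""
    config = config or PipelineConfig()
    scheme = scheme or ScoringScheme()
    genome_map = {g.id: g for g in genome}
    genome_len = sum(len(g.seq) for g in genome)
    hits = search_genome(consensus, genome, config, scheme, indexes=indexes)
    kept = filter_fragments(hits, config.min_fragment_len)
    copies = merge_adjacent(kept, config)
    for copy in copies:
        copy_divergence(copy, consensus, genome_map, scheme)
    table = activity_landscape(copies, config)
    cov = genome_coverage(copies, genome_len)
    logger.info(
        "survey %s: %d copies, %.3f%% of genome", consensus.id, len(copies), 100 * cov
    )
    return FamilySurvey(consensus=consensus, copies=copies, landscape=table, coverage=cov)


def survey_pair(
    line_consensus: DnaRecord,
    side_consensus: DnaRecord,
    genome: list[DnaRecord],
    config: PipelineConfig | None = None,
    scheme: ScoringScheme | None = None,
) -> dict[str, FamilySurvey]:
    """Survey a partner LINE and its SIDE in one genome, sharing the k-mer
    index between the two scans."""
    indexes: dict[str, GenomeIndex] = {}
    return {
        "LINE": survey_family(line_consensus, genome, config, scheme, indexes),
        "SIDE": survey_family(side_consensus, genome, config, scheme, indexes),
    }
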