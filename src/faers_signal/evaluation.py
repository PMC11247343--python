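"""Operating characteristics of the screening rule on simulated databases.

Answers the two calibration questions every disproportionality screen
raises: how often is a planted drug-PT association of a given strength
recovered (power), and how often is an association flagged where none was
planted (false-flag rate)?  Replicated generation → deduplication →
ROR screening over seeded replicates of a :class:`SimulationConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .io import deduplicate
from .model import normalize_term
from .signal import screen_signals
from .simulate import SimulationConfig, expected_cell_probabilities, generate


@dataclass(frozen=True)
class ScreeningCharacteristics:
    """Replicate tallies of planted-pair recovery and unplanted flags."""

    n_replicates: int
    #: (drug, pt) -> number of replicates in which the pair was flagged
    planted_flagged: Mapping[tuple[str, str], int]
    #: (drug, pt) -> analytic expected case count a per replicate
    expected_a: Mapping[tuple[str, str], float]
    unplanted_flagged: int
    unplanted_evaluations: int

    def recovery_fraction(self, pair: tuple[str, str]) -> float:
        return self.planted_flagged[pair] / self.n_replicates

    @property
    def false_flag_rate(self) -> float:
        if not self.unplanted_evaluations:
            return 0.0
        return self.unplanted_flagged / self.unplanted_evaluations


def screening_operating_characteristics(
    config: SimulationConfig,
    drugs: Sequence[str],
    n_replicates: int = 100,
    base_seed: int = 0,
) -> ScreeningCharacteristics:
    """Replicate the generate → deduplicate → screen cycle and tally flags.

    Every candidate PT of the simulated universe is screened against every
    listed drug in each replicate (replicate ``i`` uses seed
    ``base_seed + i``); a (drug, PT) pair counts as planted when the config
    lists an enrichment for it.
    """
    drugs = [normalize_term(d) for d in drugs]
    pts = [normalize_term(p.name) for p in config.pts]
    planted = {
        (normalize_term(e.drug), normalize_term(e.pt)) for e in config.enrichments
    }
    expected_a = {
        pair: config.n_reports * expected_cell_probabilities(config, *pair)[0]
        for pair in sorted(planted)
        if pair[0] in drugs
    }
    planted_flagged = {pair: 0 for pair in expected_a}
    unplanted_flagged = 0
    unplanted_evaluations = 0
    for i in range(n_replicates):
        reports, _ = generate(config, seed=base_seed + i)
        dedup = deduplicate(reports)
        for drug in drugs:
            for result in screen_signals(dedup, [drug], pts, drug_name=drug):
                pair = (drug, result.pt)
                if pair in planted:
                    if pair in planted_flagged and result.is_signal:
                        planted_flagged[pair] += 1
                else:
                    unplanted_evaluations += 1
                    if result.is_signal:
                        unplanted_flagged += 1
    return ScreeningCharacteristics(
        n_replicates=n_replicates,
        planted_flagged=planted_flagged,
        expected_a=expected_a,
        unplanted_flagged=unplanted_flagged,
        unplanted_evaluations=unplanted_evaluations,
    )
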