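"""Canonical validation study design: the two-deme IM scan benchmark.

These are the conditions under which the framework's power and asymmetry
behaviour are evaluated: a two-deme isolation-with-migration model with
N1 = N2 = 10,000 diploids, mutation rate 5e-7 per bp per generation, focal
migration priors log10 M12, log10 M21 ~ U[-4, 3], 5-kb non-recombining loci,
and pseudogenomes of neutral plus survival-conditioned selected loci. Desk
runs use 200 neutral + 50 selected loci and a 50,000-row reference table
(the full-scale design of 1000 + 50 loci and 250,000 simulations is a
configuration change, not a code change).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .abc_glm import ReferenceTable, StatTransform, build_reference_table, fit_transform
from .demography import DemographicModel, default_migration_priors, two_deme_im_model
from .selection import Pseudogenome, SelectionRegime, build_pseudogenome

MUTATION_RATE = 5e-7  #: per bp per generation
LOCUS_LENGTH = 5000  #: bp
DIPLOID_SIZE = 10_000  #: per deme
NEUTRAL_M_GRID = (0.5, 5.0, 50.0)  #: migrants per generation
SELECTION_GRID = (0.0, 0.001, 0.01, 0.1)
ONSET_GRID = (400.0, 4_000.0, 40_000.0, 400_000.0)
STANDING_FREQUENCY = 0.1


@dataclass
class StudyDesign:
    """Desk-scale defaults for the validation experiments."""

    model: DemographicModel = field(default_factory=lambda: two_deme_im_model(
        n1=DIPLOID_SIZE, n2=DIPLOID_SIZE, mutation_rate=MUTATION_RATE))
    priors: list = field(default_factory=default_migration_priors)
    sample_config: dict = field(default_factory=lambda: {"deme1": 20, "deme2": 20})
    locus_length: int = LOCUS_LENGTH
    n_reference: int = 50_000
    n_neutral: int = 200
    n_selected: int = 50
    sfs_bins: int = 4
    pls_components: int = 8
    n_retain: int = 1000
    grid_shape: tuple = (33, 33)

    @property
    def pops(self) -> list:
        return list(self.sample_config)

    def reference_table(self, rng, n_sims: int | None = None) -> ReferenceTable:
        return build_reference_table(
            self.model,
            self.priors,
            n_sims or self.n_reference,
            self.sample_config,
            self.locus_length,
            rng,
            sfs_bins=self.sfs_bins,
        )

    def transform(self, table: ReferenceTable) -> StatTransform:
        return fit_transform(table, self.pls_components)

    def pseudogenome(
        self,
        m_neutral: float,
        regime: SelectionRegime | None,
        rng,
        *,
        n_neutral: int | None = None,
        n_selected: int | None = None,
        resample_cap: int = 10_000,
    ) -> Pseudogenome:
        params = {"M12": m_neutral, "M21": m_neutral}
        return build_pseudogenome(
            self.model,
            params,
            regime,
            self.n_neutral if n_neutral is None else n_neutral,
            self.n_selected if n_selected is None else n_selected,
            self.locus_length,
            self.sample_config,
            rng,
            resample_cap=resample_cap,
        )


def benchmark_regime(s1: float = 0.1, s2: float = 0.1, t_onset: float = 40_000.0,
                     origin: str = "standing") -> SelectionRegime:
    """The workhorse selection regime of the power benchmark."""
    return SelectionRegime(s1, s2, t_onset, STANDING_FREQUENCY, STANDING_FREQUENCY, origin)
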