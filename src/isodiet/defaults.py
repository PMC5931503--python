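"""Reference source geometry and enrichment factors used as defaults.

Source means/SDs are literature muscle-tissue values for the five food
categories of the study system (landfill refuse, extensively raised
livestock, wild herbivores, carnivores, birds); the enrichment factors
are the phylogenetically imputed feather values used for the fits.
"""

from isodiet.types import SourceSpec, TEFSpec

DEFAULT_SOURCES: tuple[SourceSpec, ...] = (
    SourceSpec("landfill", mu13C=-21.67, sd13C=1.44, mu15N=5.50, sd15N=1.74),
    SourceSpec("livestock", mu13C=-25.68, sd13C=0.19, mu15N=6.07, sd15N=0.40),
    SourceSpec("wild_herbivores", mu13C=-24.22, sd13C=1.17, mu15N=2.54, sd15N=1.63),
    SourceSpec("carnivores", mu13C=-24.60, sd13C=0.70, mu15N=9.00, sd15N=2.30),
    SourceSpec("birds", mu13C=-23.67, sd13C=0.57, mu15N=6.40, sd15N=1.07),
)

DEFAULT_TEF = TEFSpec(mu13C=1.11, sd13C=1.12, mu15N=3.33, sd15N=1.18)

# Population-level feather summary (mean, SD permil) for the study's 60
# nestlings; used to reconstruct plausible nest-year observations when
# per-nest values are unavailable.
FEATHER_POPULATION_D13C = (-21.97, 1.088)
FEATHER_POPULATION_D15N = (10.08, 1.653)

# MCMC defaults.
DEFAULT_N_CHAINS = 4
DEFAULT_N_ITER = 10_000
DEFAULT_N_BURNIN = 1_000
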