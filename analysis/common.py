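"""Shared configuration for the numbered analysis drivers.

The drivers reproduce the full study workflow over the synthetic cohort:
run them in order (01 -> 08); each reads what earlier steps wrote under
``results/`` and appends its own tables there.
"""

from pathlib import Path

from cloverpop.io_formats import RunConfig
from cloverpop.simulate import SimulationConfig

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
RESULTS = ROOT / "results"

SEED = 1

RUN_CONFIG = RunConfig(
    input_counts=str(DATA / "allele_counts.tsv"),
    input_population_map=str(DATA / "population_map.tsv"),
    seed=SEED,
    n_permutations=1000,
    n_pairwise_permutations=200,
    n_fdist_simulations=8000,
)

#: the emulated survey design: 29 accessions x 10 plants, 400 targeted +
#: 296 de-novo loci, F = 0.05, four tetraploid accessions, 500x coverage
SIM_CONFIG = SimulationConfig(seed=SEED)

META = {"seed": SEED, "config_hash": RUN_CONFIG.content_hash()}
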