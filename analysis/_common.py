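"""Shared configuration for the numbered analysis scripts.

Every script reads/writes under results/analysis and uses the same demo
study: one 60-unit population across three visual areas, two stimulus
types with distinct planted coupling sets, shared slow rate modulation.
"""

from pathlib import Path

import spikenet as sn

OUT = Path("results/analysis")
SEED = 1

CONFIG = sn.RunConfig.demo(outdir=str(OUT), seed=SEED)
STIMULI = sorted(CONFIG.stimuli)
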