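"""Shared configuration for the numbered analysis drivers.

One demo profile: 120 donors, 1024x1024 px slides (~16 tiles each), a
planted 30% white-matter staining reduction in impaired donors, 10% label
noise, tenfold Monte Carlo cross-validation.
"""

from lfbmil.config import RunConfig

CONFIG = RunConfig(outdir="results/run", seed=1)
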