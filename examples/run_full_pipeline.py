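"""Run the complete five-color experiment end to end.

One call simulates the three spectral channels in confocal and STED mode,
phasor-transforms and calibrates them, separates the five fluorochromes
(two per shared channel by unmixing, CF680R by exclusion filtering of the
reflection), and writes lifetime, crosstalk and FRC tables plus all
intermediate images into a run directory.  Rerunning the same config
reproduces every number bit-exactly.
"""

import pandas as pd

from phasorsted import RunConfig, run_five_color

config = RunConfig(preset="five_color", size=128, seed=1,
                   out_dir="scratch/example_run")
out = run_five_color(config)
print(f"run directory: {out}\n")

taus = pd.read_csv(out / "recovered_lifetimes.csv")
print("recovered peak lifetimes (ns):")
print(taus.to_string(index=False))
print("\nconfocal ground truth: mitochondria 2.2, actin 3.2, vimentin 2.6, "
      "membrane 1.8, pores 1.7")

frc = pd.read_csv(out / "frc.csv")
print("\nFRC resolution (nm) per separated component:")
print(frc.pivot_table(index="structure", columns="arm",
                      values="resolution_nm").round(0).to_string())
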