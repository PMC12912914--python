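#!/usr/bin/env python
"""Collate the stage outputs into results/summary.{md,json}."""

from astraj.pipeline import run

run("report", outdir="results")
print(open("results/summary.md").read())
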