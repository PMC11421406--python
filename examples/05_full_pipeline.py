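"""The full analysis pipeline on the default synthetic study.

Simulates the complete design (27 listeners x 9 maskers x 5 SNRs x 5
sentences = 6075 trials) with the standard missingness structure, scores
both channels, computes timing measures, aggregates to the 270
listener x masker-type x SNR cells, and fits the five stepwise
regression models.  The printed report mirrors a results section:
channel agreement (ICC), model coefficients, per-participant
correlations between timing and self-reported effort.
"""

from speechresp import pipeline

bundle = pipeline.run(pipeline.PipelineConfig(seed=1))
print(pipeline.report(bundle))
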