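"""Run CWINCA feature selection end to end on a planted fixture.

Prints the cumulative-weight search window, the per-size 1-NN CV losses,
and the chosen subset.  The three informative columns should survive and
the selected subset's loss should not exceed the all-feature loss.
"""

from cwinca import (
    CwincaConfig,
    NcaConfig,
    PlantedSpec,
    cwinca_select,
    knn_cv_loss,
    make_planted_features,
    minmax_normalize,
)

data = make_planted_features(PlantedSpec(seed=0))
cfg = CwincaConfig(seed=0)
trace = cwinca_select(data, cfg, NcaConfig(seed=0))

print(f"search window: sizes {trace.start_size}..{trace.stop_size} of {data.n_features}")
for size, loss in zip(range(trace.start_size, trace.stop_size + 1), trace.losses):
    marker = " <- chosen" if size == trace.chosen_size else ""
    print(f"  size {size:2d}: CV loss {loss:.3f}{marker}")
print(f"selected: {trace.selected_features}")
full = knn_cv_loss(minmax_normalize(data, cfg.epsilon), cfg)
print(f"all-feature loss {full:.3f} vs selected loss {trace.best_loss:.3f}")
# A lower selected loss means discarding the noise columns helped the
# 1-NN classifier, the effect the selector exists to deliver.
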