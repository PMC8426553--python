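"""Plot where a trained model attends within one sequence.

Trains a small model on salient-window data, then prints (and optionally
saves as a figure) the per-head attention trace of one held-out sequence
against time.  The peak should fall inside the sequence's salient span.
"""

import numpy as np

from attnspeech.model import ModelConfig
from attnspeech.pipeline import PipelineConfig, normalize_features, train, visualize_attention
from attnspeech.study import study_spec
from attnspeech.synthetic import gen_sequences

dataset = gen_sequences(study_spec(seed=1))
normed, _ = normalize_features(dataset.sequences, dataset.sequences)

cfg = PipelineConfig(
    model=ModelConfig(input_size=16, lstm_hidden=(32, 16), heads=4,
                      fc_sizes=(128, 12), lr=1e-3, batch=64, seed=1),
    epochs=40, patience=40, seed=1,
)
result = train(normed[:-1], dataset.labels[:-1], cfg)

segment = normed[-1]
span = dataset.salient_spans[-1]
trace = visualize_attention(result.model, segment, hop=0.010)

mean_trace = trace.scores.mean(axis=0)
peak = int(np.argmax(mean_trace))
print(f"sequence length {segment.shape[0]} frames; salient span frames {span}")
print(f"attention peak at frame {peak} (t = {trace.times[peak]:.2f} s), "
      f"{'inside' if span[0] <= peak < span[1] else 'outside'} the salient span")
print(f"mass inside span: {mean_trace[span[0]:span[1]].sum():.3f} "
      f"(uniform would be {(span[1]-span[0])/segment.shape[0]:.3f})")

try:
    import matplotlib

    matplotlib.use("Agg")
    ax = trace.plot()
    ax.axvspan(trace.times[span[0]], trace.times[span[1] - 1], alpha=0.2, color="red")
    ax.figure.savefig("attention_trace.png", dpi=120)
    print("saved attention_trace.png")
except ImportError:
    pass
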