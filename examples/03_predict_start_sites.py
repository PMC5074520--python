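"""Score every candidate start site of one transcript with a trained model.

Mirrors the predict workflow: enumerate all AUG / near-cognate codons in the
5' UTR that have a downstream in-frame stop and full 99-nt flanks, compute
their features, and report the clamped initiation confidence plus qualitative
class per site.
"""

from tiscall import SimulationParams, TrainingConfig
from tiscall.predict import predict_candidates
from tiscall.synthetic import end_to_end_fixture

result = end_to_end_fixture(
    SimulationParams(n_transcripts=25, seed=7),
    TrainingConfig(seed=7, n_repeats=2),
    use_orthologs=False,
)
model = result.report.best_model
transcript = result.dataset.transcripts[2]

df = predict_candidates(transcript, model, result.efficiency)
print(f"transcript {transcript.id}: 5' UTR {len(transcript.utr5)} nt, "
      f"{len(df)} candidate start sites\n")
print(df.round(3).to_string(index=False))

called = df[df["confidence"] >= model.threshold]
print(f"\n{len(called)} candidate(s) above the decision threshold "
      f"t = {model.threshold:.2f}; positions are Kozak offsets relative to")
print("the annotated start (+1), so negative values lie in the 5' UTR.")
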