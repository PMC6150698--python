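"""The full screen analysis: null model, bootstrap threshold, network.

Runs the packaged fixture screen (10 candidate pairs with planted ground
truth + 20 non-overlapping controls) end to end and prints the resulting
connectivity calls.
"""

from pathlib import Path

from cxscreen.config import PipelineConfig
from cxscreen.pipeline import run_all

config = PipelineConfig.from_yaml(Path(__file__).parent / "fixture_screen.yaml")
result = run_all(config, "scratch/example_run")

model = result["model"]
print(f"null model over {model.n_null} non-overlapping pairs; significance "
      f"threshold: squared Mahalanobis distance > {model.threshold:.1f}")

edges = result["edges_df"]
for row in edges[edges["significant"]].itertuples():
    kind = "excitatory" if row.sign > 0 else "inhibitory"
    print(f"  {row.pre} -> {row.post}: {kind}, strength {row.strength:.0f}, "
          f"reliability {row.reliability:.2f}")

comp = result["comparison"]
hits = comp[~comp["control"]]["correct"].sum()
print(f"planted connectome recovered: {hits}/10 candidate pairs correct, "
      f"{int(comp[comp['control']]['significant'].sum())}/20 controls flagged")
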