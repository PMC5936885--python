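"""Which rhythmic unit explains interbeat durations? A full recovery run.

Generates one synthetic corpus under the study conditions (two drummers,
four V-to-V duration classes 20 ms apart, 15 ms timing noise, ~7,000
intra-word interbeat durations), then fits the competing models, runs the
simultaneous contrasts and derives the duration scale.  The V-to-V model
should out-explain the syllable model, all 12 within-drummer contrasts
should separate, and the syllable analysis should show the tell-tale
artefact CV < V.
"""

from manguare.stats import (
    ModelSpec,
    backward_select,
    consistency_score,
    derive_scale,
    fit_model,
    pairwise_contrasts,
)
from manguare.synth import generate_study_corpus

corpus = generate_study_corpus(seed=42)
df = corpus.frame()
print(f"{len(corpus.messages)} aligned messages "
      f"(+{len(corpus.slipped)} excluded for slips), "
      f"{len(df)} intra-word interbeat durations\n")

fitted = {}
for unit in ("vtov", "syllable"):
    model, _ = backward_select(df, ModelSpec(unit=unit))
    fitted[unit] = model
    print(f"[{unit}] {model.formula}   adjusted R² = {model.adj_r2:.4f}")
print("-> the V-to-V labelling explains more variance with fewer levels\n")

contrasts = pairwise_contrasts(fitted["vtov"], seed=42)
n_sig = sum(r.significant for r in contrasts.results)
print(f"V-to-V contrasts: {n_sig}/{len(contrasts)} significant")
for drummer in ("1", "2"):
    scale = derive_scale(contrasts, group=drummer)
    means_ms = [f"{m * 1000:.0f}" for m in scale.class_means]
    print(f"  drummer {drummer}: {scale}   (class means {means_ms} ms)")

syl_contrasts = pairwise_contrasts(fitted["syllable"], seed=42)
print(f"\nsyllable scale, drummer 1: "
      f"{derive_scale(syl_contrasts, group='1')}")
for hypothesis in ("mora", "vowel-length"):
    rep = consistency_score(syl_contrasts, hypothesis)
    print(f"  {hypothesis}: {rep.inconsistent}/{rep.total} pairwise "
          f"verdicts inconsistent ({rep.counts()})")
# The binary weight hypotheses cannot absorb a four-way duration scale:
# many pairs differ that they say should not, and vice versa.
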