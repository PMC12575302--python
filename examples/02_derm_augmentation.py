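"""DERM augmentation: replace / mask / keep branches on one sequence.

The per-sequence random number RN picks the branch: RN < 0.3 replaces every
entity surface with a same-type dictionary term, 0.3 <= RN < 0.6 masks the
entity tokens, RN >= 0.6 leaves the sequence alone.  Injecting RN shows each
branch deterministically; the corpus pass then shows the empirical rates.
"""

from collections import Counter

from emrkg import synthetic
from emrkg.corpus_io import TagSequence
from emrkg.derm import DermConfig, augment_corpus, derm_transform

cfg = synthetic.GeneratorConfig(seed=5)
dicts = synthetic.generate_dictionaries(cfg)

seq = TagSequence(
    list("xy") + list(dicts["diseases"][0]) + ["z"],
    ["O", "O", "B-diseases"]
    + ["I-diseases"] * (len(dicts["diseases"][0]) - 1)
    + ["O"],
)
dcfg = DermConfig(dictionaries=dicts, seed=0)
for rn in (0.1, 0.45, 0.9):
    out, branch = derm_transform(seq, dcfg, rng_value=rn)
    print(f"RN={rn:.2f} -> {branch:7s} tokens: {''.join(out.tokens)}")

seqs = synthetic.generate_tag_sequences(cfg, dicts)
_, log = augment_corpus(seqs * (10_000 // len(seqs) + 1), dcfg)
rates = {b: n / len(log) for b, n in Counter(log).items()}
print("empirical branch rates over", len(log), "sequences:",
      {b: round(r, 3) for b, r in sorted(rates.items())},
      "(expected replace 0.3, mask 0.3, keep 0.4)")
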