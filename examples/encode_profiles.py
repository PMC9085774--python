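"""Encode raw actions into conditional-action symbols and player profiles.

The previous round's (own, opponent) actions form the context of the current
decision; context plus current action maps to one of 8 integers, e.g.
(CD)D -> 3.  Profiles count how often each context occurred and how often
the response to it was cooperative.
"""

from ipdinfer import (
    SYMBOL_LABELS,
    archetype,
    encode_table,
    profile_table,
    sequence_encode,
    simulate,
)

# a hand-checkable pair: TFT meets AllD, so TFT reciprocates defection
result = simulate([archetype("TFT"), archetype("AllD")], n_rounds=6, mode="FP", seed=0)
for seq in encode_table(result.games):
    labels = [SYMBOL_LABELS[s] for s in seq.symbols]
    print(f"{seq.player}: symbols {[int(s) for s in seq.symbols]} = {labels}")

print("\nper-player context counts (n_*) and cooperative responses (c_*):")
print(profile_table(encode_table(result.games)).to_string())

print("\ndirect encoding of own=C,D,D vs opp=D,D,D:",
      [int(s) for s in sequence_encode("CDD", "DDD")])
print("(round 2: context CD, action D -> 3; round 3: context DD, action D -> 7)")
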