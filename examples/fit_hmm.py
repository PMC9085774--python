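"""Fit a left-to-right HMM to pooled conditional-action sequences.

The model starts in state s1 and can only move forward through the state
order; emissions over the 8 conditional actions describe the behavior in
each phase.  Here the data come from TFT players recovering cooperation
against noisy TFT partners, a two-phase structure the state count selection
should detect when present.
"""

from ipdinfer import (
    archetype,
    encode_table,
    prune_for_display,
    select_states,
    simulate,
    to_dot,
)

result = simulate([archetype("TFT", noise=0.05)] * 20, n_rounds=100, mode="FP", seed=2)
seqs = [seq.symbols for seq in encode_table(result.games)]

model = select_states(seqs, s_max=4, criterion="delta", seed=0)
print(f"selected {model.n_states} hidden state(s)")
print("score table (S, loglik, BIC):")
for row in model.selection_table:
    print(f"  S={row['S']}: loglik={row['loglik']:.1f}, bic={row['bic']:.1f}")

print("\nDOT rendering of the display model (emissions <= 0.05 and")
print("transitions <= 0.01 hidden for readability):")
print(to_dot(prune_for_display(model)))
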