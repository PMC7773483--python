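"""How the parent-set proposal steers the sampler toward sparse graphs.

Prints the add / remove / swap action probabilities as the current parent
count s moves past the prior-implied reference size s_hat.
"""

from ssps.mcmc import action_probabilities

V, SHAT = 40, 5.0
print(f"|V| = {V}, reference size s_hat = {SHAT:g}\n")
print(f"{'s':>4} {'p(add)':>8} {'p(remove)':>10} {'p(swap)':>8}")
for s in (0, 1, 3, 5, 8, 15, 30, 40):
    add, remove, swap = action_probabilities(s, SHAT, V)
    print(f"{s:>4} {add:>8.3f} {remove:>10.3f} {swap:>8.3f}")

print("\nadd is certain at s=0, remove is certain at s=|V|, and all three "
      "actions are equally likely at s = s_hat.")
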