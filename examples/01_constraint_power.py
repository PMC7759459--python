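"""How many genome positions stay invariant purely by chance?

Under a homogeneous Poisson substitution model, a site is unchanged
across an entire phylogeny with probability e^(-L), where L is the
total tree branch length in substitutions per site. For a 240-species
mammal alignment (L = 16.6) and a human-sized genome this sets the
false-positive floor for calling evolutionary constraint.
"""

import sohscan

G = 3.1e9   # human genome, bp
L = 16.6    # total branch length, substitutions per site

frac = sohscan.fraction_invariant(L)
sites = sohscan.expected_invariant_sites(G, L)

print(f"P(site invariant by chance)    = {frac:.3g}  ({100 * frac:.6f}%)")
print(f"expected invariant sites       = {sites:.1f}  (~{round(sites)} positions)")
print(f"branch length for 1 chance site= {sohscan.required_branch_length(G, 1):.2f} subs/site")
print()
print("Any position conserved across all species beyond these ~191 is")
print("evidence of purifying selection rather than mutational luck.")
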