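"""Limiting feature-diversity loss curves on birth-death trees.

For a supercritical birth-death tree (speciation lam, extinction mu) with
feature gain r and loss nu, the large-t fraction of expected feature
diversity surviving a field-of-bullets event with survival probability s is
phi_FD(s) = s I(s)/I(1), a function of s and the ratios rho1 = mu/lam,
rho2 = nu/lam only.  At nu = 0 it coincides with the phylogenetic-diversity
curve phi_PD(s); as nu grows it falls toward the species-loss line y = s.
"""

from featdiv import (
    BDParams,
    DerivedRatios,
    FeatureParams,
    expected_singletons,
    fd_per_species_limit,
    phi_fd_limit,
    phi_pd,
)

print("surviving fraction of expected diversity at s = 0.5 (pure-birth tree):")
print(f"  phylogenetic diversity (nu=0): {phi_pd(0.0, 0.5):.4f}")
for rho2 in (0.5, 1.0, 2.0, 10.0):
    v = phi_fd_limit(DerivedRatios(rho1=0.0, rho2=rho2), 0.5)
    print(f"  feature diversity, nu/lam={rho2:>4g}: {v:.4f}")
print("  (feature loss always costs more diversity than the PD curve predicts;"
      " the curves approach y = s as nu/lam grows)")

# expected features per surviving species in the large-t limit
ratios = DerivedRatios.from_rates(lam=1.0, mu=0.2, nu=0.5)
per_sp = fd_per_species_limit(ratios, r=0.3, nu=0.5, s=0.5)
print(f"\nlimit of E[FD]/(s e^{{(lam-mu)t}}) at s=0.5: {per_sp:.4f} features "
      "per surviving species")

# expected number of features confined to a single extant species at time t
bd, fp = BDParams(lam=1.0, mu=0.2), FeatureParams(r=0.3, nu=0.5)
for t in (2.0, 4.0, 8.0):
    print(f"expected singleton features at t={t:g}: "
          f"{expected_singletons(bd, fp, t):.3f}")
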