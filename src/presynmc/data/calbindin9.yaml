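# Calbindin-D28k calcium buffer: two high-affinity (H) and two medium-affinity
# (M) binding sites, giving nine occupancy states HaMb, a,b in {0,1,2}.
#
# k_on in 1/(M*s), k_off in 1/s, per individual site.  Statistical
# (stoichiometric) multiplicity for two identical sites -- factor 2 for
# binding the first site and for unbinding from the doubly-occupied state --
# is applied by the scheme builder, not baked into these constants.
#
# Source: Naegerl et al. (2000) calbindin kinetics, as used in Bartol et al.
# (2015).
version: 1
scheme: calbindin9
high:   {k_on: 1.1e+7, k_off: 2.6}
medium: {k_on: 8.7e+7, k_off: 35.8}
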