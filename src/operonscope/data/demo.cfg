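# demo run: small cohort, every stage exercised in a few minutes
seed = 1
n_species = 2
copies_per_species = 2
target_identity = 0.94
n_reads = 30
group_sizes = 2, 2, 2, 2
sub_rate = 0.05
ins_rate = 0.015
del_rate = 0.015
wt_sed_species = sp02
n_perm = 499
top_n = 10
min_reads = 5
n_bootstrap = 100
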