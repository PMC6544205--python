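affymetrix_1
affymetrix_2
genotyping_array
batch
plate_name
well
cluster_cr
dqc
internal_pico_ng_ul
submitted_gender
inferred_gender
x_intensity
y_intensity
submitted_plate_name
submitted_well
sample_qc_missing_rate
heterozygosity
heterozygosity_pc_corrected
het_missing_outliers
putative_sex_chromosome_aneuploidy
in_kinship_table
excluded_from_kinship_inference
excess_relatives
in_white_british_ancestry_subset
used_in_pca_calculation
pc1
pc2
pc3
pc4
pc5
pc6
pc7
pc8
pc9
pc10
pc11
pc12
pc13
pc14
pc15
pc16
pc17
pc18
pc19
pc20
pc21
pc22
pc23
pc24
pc25
pc26
pc27
pc28
pc29
pc30
pc31
pc32
pc33
pc34
pc35
pc36
pc37
pc38
pc39
pc40
in_phasing_input_chr1_22
in_phasing_input_chrx
in_phasing_input_chrxy
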