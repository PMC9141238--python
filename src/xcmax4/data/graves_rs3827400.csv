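# rs3827400 (GPR174, chromosome X) genotype counts for Graves' disease,
# from two published case-control studies (Han Chinese two-stage GWAS and
# two Caucasian cohorts). Risk allele T (internally A), normal allele C.
# Female columns count TT/TC/CC as AA/Aa/aa; male columns count T/C as A/a.
dataset,group,AA,Aa,aa,A,a
chu_stage1,female_case,444,508,163,,
chu_stage1,male_case,,,,232,109
chu_stage1,female_control,367,541,219,,
chu_stage1,male_control,,,,186,172
chu_stage2,female_case,1298,1606,471,,
chu_stage2,male_case,,,,606,284
chu_stage2,female_control,957,1344,584,,
chu_stage2,male_control,,,,526,396
szymanski_warsaw,female_case,85,205,146,,
szymanski_warsaw,male_case,,,,51,53
szymanski_warsaw,female_control,81,229,188,,
szymanski_warsaw,male_control,,,,104,146
szymanski_gliwice,female_case,30,78,58,,
szymanski_gliwice,male_case,,,,11,20
szymanski_gliwice,female_control,27,73,71,,
szymanski_gliwice,male_control,,,,10,20
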