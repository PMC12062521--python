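# Static documentation table: published serum/plasma NfL upper reference
# values by age from selected healthy-cohort studies (Simoa platform).
# Not consumed by any computation in this package.
study,n_subjects,study_site,statistical_analysis,cutoff_definition,nfl_age20_pg_ml,nfl_age30_pg_ml,nfl_age40_pg_ml,nfl_age50_pg_ml,nfl_age60_pg_ml
Chen 2021,146,China,subgroup descriptive analysis,P95,8.4,9.2,22.2,34.1,68.3
Hviid 2020,342,Denmark,linear regression on log-transformed NfL,P97.5,7.4,9.9,13.1,17.5,23.3
Bornhorst 2022,1100,USA,linear regression on log-transformed NfL,P97.5,8.4,11.4,15.4,20.8,28.0
Benkert 2022,5390,"USA, Netherlands, Switzerland, Germany",GAMLSS with Z-score derivation,Z>2.0 (P97.72),8.5,11.5,14.2,18.1,23.8
Vermunt 2022,833,Netherlands,quantile regression on log-transformed NfL,P95,9.0,10.0,12.0,14.0,19.0
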