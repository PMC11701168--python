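scenario,age_group,outcome,mean,mc_sd
base,3-4,person_years,115339,436
base,5-9,person_years,526680,1484
base,10-14,person_years,729025,1668
base,15-18,person_years,611817,1429
base,overall,person_years,1982861,4161
flat,3-4,person_years,128577,442
flat,5-9,person_years,545222,1383
flat,10-14,person_years,734116,1494
flat,15-18,person_years,612159,1322
flat,overall,person_years,2020074,3785
mid,3-4,person_years,122560,429
mid,5-9,person_years,536593,1339
mid,10-14,person_years,731875,1552
mid,15-18,person_years,612150,1327
mid,overall,person_years,2003178,3718
base,3-4,incident_cases,79976,304
base,5-9,incident_cases,62621,234
base,10-14,incident_cases,24914,143
base,15-18,incident_cases,15882,113
base,overall,incident_cases,183392,417
flat,3-4,incident_cases,89362,279
flat,5-9,incident_cases,63301,226
flat,10-14,incident_cases,24897,148
flat,15-18,incident_cases,15885,130
flat,overall,incident_cases,193445,411
mid,3-4,incident_cases,85110,306
mid,5-9,incident_cases,62983,242
mid,10-14,incident_cases,24896,164
mid,15-18,incident_cases,15889,134
mid,overall,incident_cases,188878,425
base,3-4,exacerbations,142426,659
base,5-9,exacerbations,157404,601
base,10-14,exacerbations,55877,300
base,15-18,exacerbations,27365,176
base,overall,exacerbations,383072,1129
flat,3-4,exacerbations,158505,608
flat,5-9,exacerbations,164192,634
flat,10-14,exacerbations,56252,270
flat,15-18,exacerbations,27404,157
flat,overall,exacerbations,406352,1130
mid,3-4,exacerbations,151285,715
mid,5-9,exacerbations,161045,651
mid,10-14,exacerbations,56081,276
mid,15-18,exacerbations,27389,192
mid,overall,exacerbations,395800,1172
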