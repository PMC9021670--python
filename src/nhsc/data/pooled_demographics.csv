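insurer_id,age_band,gender,residents,hospitalized_persons,hospitalizations
pooled,0-14,male,215,,
pooled,0-14,female,323,,
pooled,15-19,male,459,,
pooled,15-19,female,291,,
pooled,20-24,male,625,,
pooled,20-24,female,538,,
pooled,25-29,male,1035,,
pooled,25-29,female,916,,
pooled,30-34,male,1276,,
pooled,30-34,female,949,,
pooled,35-39,male,1257,,
pooled,35-39,female,996,,
pooled,40-44,male,1376,,
pooled,40-44,female,1019,,
pooled,45-49,male,1921,,
pooled,45-49,female,1711,,
pooled,50-54,male,3112,,
pooled,50-54,female,2658,,
pooled,55-59,male,3903,,
pooled,55-59,female,3292,,
pooled,60-64,male,4298,,
pooled,60-64,female,3563,,
pooled,65-69,male,5011,,
pooled,65-69,female,4540,,
pooled,70-74,male,5271,,
pooled,70-74,female,6638,,
pooled,75-79,male,9048,,
pooled,75-79,female,16556,,
pooled,80-84,male,10454,,
pooled,80-84,female,29364,,
pooled,85-89,male,9917,,
pooled,85-89,female,40872,,
pooled,>=90,male,8140,,
pooled,>=90,female,60692,,
pooled,all,male,67317,32275,62302
pooled,all,female,174919,74679,124269
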