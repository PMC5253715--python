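category,key,value
procedure,lens_extraction_daycase,866
procedure,lens_extraction_inpatient,2157
procedure,laser_iridotomy,118
procedure,lens_capsulotomy,121
procedure,iridoplasty,172
procedure,trabeculectomy,1140
procedure,cataract_surgery,866
procedure,other_glaucoma_procedure,500
procedure,ophthalmology_outpatient,80
contact,gp_surgery_visit,43
contact,gp_home_visit,53.58
contact,gp_phone,26
contact,community_optician,62
contact,district_nurse,12.4
contact,practice_nurse,10.59
medication_monthly,iop_lowering,5.0
wage,paid_hourly,13.08
wage,unpaid_hourly,7.0
meta,currency_year,2012-2013
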