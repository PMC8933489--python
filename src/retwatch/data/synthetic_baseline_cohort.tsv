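patient_id	ret_class	baseline_detected	best_response	duration_weeks	on_treatment
P001	mutant	True	PR	30.0	False
P002	mutant	True	PR	30.0	False
P003	mutant	True	PR	30.0	False
P004	mutant	True	PR	30.0	False
P005	mutant	True	PR	30.0	False
P006	mutant	True	PR	30.0	False
P007	mutant	True	PR	30.0	False
P008	mutant	True	PR	30.0	False
P009	mutant	True	PR	30.0	False
P010	mutant	True	PR	30.0	False
P011	mutant	True	PR	30.0	False
P012	mutant	True	PR	30.0	False
P013	mutant	True	PR	30.0	False
P014	mutant	True	PR	30.0	False
P015	mutant	True	PR	30.0	False
P016	mutant	True	PR	30.0	False
P017	mutant	True	PR	30.0	False
P018	mutant	True	PR	30.0	False
P019	mutant	False	PR	30.0	False
P020	fusion	True	PR	30.0	False
P021	fusion	True	PR	30.0	False
P022	fusion	True	PR	30.0	False
P023	fusion	True	PR	30.0	False
P024	fusion	True	PR	30.0	False
P025	fusion	True	PR	30.0	False
P026	fusion	True	PR	30.0	False
P027	fusion	True	PR	30.0	False
P028	fusion	True	PR	30.0	False
P029	fusion	True	PR	30.0	False
P030	fusion	True	PR	30.0	False
P031	fusion	True	PR	30.0	False
P032	fusion	True	PR	30.0	False
P033	fusion	True	PR	30.0	False
P034	fusion	True	PR	30.0	False
P035	fusion	True	PR	30.0	False
P036	fusion	True	PR	30.0	False
P037	fusion	True	PR	30.0	False
P038	fusion	True	PR	30.0	False
P039	fusion	True	PR	30.0	False
P040	fusion	True	PR	30.0	False
P041	fusion	True	PR	30.0	False
P042	fusion	True	PR	30.0	False
P043	fusion	True	PR	30.0	False
P044	fusion	True	PR	30.0	False
P045	fusion	True	PR	30.0	False
P046	fusion	True	PR	30.0	False
P047	fusion	True	PR	30.0	False
P048	fusion	True	PR	30.0	False
P049	fusion	True	PR	30.0	False
P050	fusion	True	PR	30.0	False
P051	fusion	True	PR	30.0	False
P052	fusion	True	PR	30.0	False
P053	fusion	True	PR	30.0	False
P054	fusion	True	PR	30.0	False
P055	fusion	True	PR	30.0	False
P056	fusion	False	PR	30.0	False
P057	fusion	False	PR	30.0	False
P058	fusion	False	PR	30.0	False
P059	fusion	False	PR	30.0	False
P060	fusion	False	PR	30.0	False
P061	fusion	False	PR	30.0	False
P062	fusion	False	PR	30.0	False
P063	fusion	False	PR	30.0	False
P064	fusion	False	PR	30.0	False
P065	fusion	False	PR	30.0	False
P066	fusion	False	PR	30.0	False
P067	fusion	False	PR	30.0	False
P068	fusion	False	PR	30.0	False
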