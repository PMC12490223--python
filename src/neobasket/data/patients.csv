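# Individual patient data, transcribed from the trial publication (22 patients;
# 14 colon T4 / 8 rectal). Durations in months from start of study treatment.
# Encoding notes:
#  - R4: the published surgery cell reads "no", but the row carries a time to
#    surgery (9.7), a pathological stage (ypT0N0) and TRG 0, and the rectal
#    per-protocol set of 6 operated patients only reconciles if R4 was operated;
#    encoded surgery=true.
#  - r0 is not reported per patient; set true for every operated patient
#    (consistent with the 100% per-protocol R0 rate) and NA otherwise.
#  - efs_months: only R7 has an event (clinical complete response at month 6,
#    regional-node progression 3 months later -> event at 9.0); all other
#    patients are event-free and censored at their recorded follow-up.
#  - dfs runs from surgery: followup_months - tts_months for operated patients.
id,cohort,age,sex,ecog,lynch,clinical_t,clinical_n_positive,site,regimen,kras,nras,braf,surgery,cycles_preop,cycles_postop,tts_months,yp_t,yp_n,trg,r0,ccr,watch_and_wait,efs_months,efs_event,dfs_months,dfs_event,os_months,os_event,followup_months
C1,colon,66,male,1,unknown,T4a,true,hepatic flexure,TORI+IRI+BEV,unknown,unknown,unknown,true,3,9,2.6,ypT4a,ypN0,3,true,false,false,33.5,false,30.9,false,33.5,false,33.5
C2,colon,50,male,1,unknown,T4a,true,ascending colon,TORI+IRI+BEV,unknown,unknown,unknown,true,4,2,2.5,ypT0,ypN0,0,true,false,false,32.3,false,29.8,false,32.3,false,32.3
C3,colon,31,male,0,yes,T4a,true,transverse colon,TORI,wild,wild,wild,true,9,0,5.6,ypT0,ypN0,0,true,false,false,26.3,false,20.7,false,26.3,false,26.3
C4,colon,57,female,0,unknown,T4a,false,ascending colon,TORI+IRI+BEV,unknown,unknown,unknown,true,3,6,3.1,ypT0,ypN0,0,true,false,false,27.7,false,24.6,false,27.7,false,27.7
C5,colon,67,male,1,unknown,T4a,true,sigmoid colon,TORI+IRI+BEV,mutant,wild,wild,true,9,0,6.0,ypT0,ypN0,0,true,false,false,27.0,false,21.0,false,27.0,false,27.0
C6,colon,41,male,0,unknown,T4a,true,hepatic flexure,TORI+IRI+BEV,unknown,unknown,unknown,true,3,9,2.0,ypT0,ypN0,0,true,false,false,25.7,false,23.7,false,25.7,false,25.7
C7,colon,33,female,0,no,T4b,true,sigmoid colon,TORI,mutant,wild,wild,true,6,6,3.5,ypT1,ypN1,1,true,false,false,24.0,false,20.5,false,24.0,false,24.0
C8,colon,34,male,0,no,T4a,false,hepatic flexure,TORI,mutant,wild,wild,true,4,0,2.1,ypT0,ypN0,0,true,false,false,20.5,false,18.4,false,20.5,false,20.5
C9,colon,69,male,0,no,T4b,true,hepatic flexure,TORI,mutant,wild,wild,true,3,9,1.8,ypT3,ypN1a,1,true,false,false,22.6,false,20.8,false,22.6,false,22.6
C10,colon,43,male,0,no,T4a,true,descending colon,TORI+IRI,wild,wild,wild,true,3,7,1.8,ypT3,ypN0,2,true,false,false,21.6,false,19.8,false,21.6,false,21.6
C11,colon,50,male,1,yes,T4a,true,hepatic flexure,TORI+IRI+BEV,mutant,wild,wild,true,5,7,2.8,ypT0,ypN0,0,true,false,false,16.0,false,13.2,false,16.0,false,16.0
C12,colon,26,male,1,yes,T4a,true,hepatic flexure,TORI,unknown,unknown,unknown,true,9,0,3.9,ypT0,ypN0,0,true,false,false,11.1,false,7.2,false,11.1,false,11.1
C13,colon,69,male,0,yes,T4a,true,sigmoid colon,TORI,mutant,wild,wild,false,12,0,NA,NA,NA,NA,NA,true,true,8.0,false,NA,NA,8.0,false,8.0
C14,colon,34,male,1,yes,T4a,true,transverse colon,TORI,mutant,wild,wild,false,12,0,NA,NA,NA,NA,NA,true,true,7.6,false,NA,NA,7.6,false,7.6
R1,rectum,19,male,0,yes,T3,true,lower rectum,TORI+IRI+BEV,mutant,wild,wild,true,7,5,4.0,ypT0,ypN0,0,true,false,false,26.5,false,22.5,false,26.5,false,26.5
R2,rectum,26,female,0,unknown,T3,true,middle rectum,TORI,unknown,unknown,unknown,true,9,3,4.4,ypT0,ypN0,0,true,false,false,24.2,false,19.8,false,24.2,false,24.2
R3,rectum,70,male,0,no,T3,true,lower rectum,TORI+IRI+BEV,wild,wild,mutant,true,9,0,7.3,ypT0,ypN0,0,true,false,false,18.2,false,10.9,false,18.2,false,18.2
R4,rectum,26,female,0,no,T3,true,lower rectum,TORI+IRI+BEV,mutant,wild,wild,true,12,0,9.7,ypT0,ypN0,0,true,false,false,17.6,false,7.9,false,17.6,false,17.6
R5,rectum,51,male,1,yes,T3,true,middle rectum,TORI+IRI,mutant,wild,wild,true,10,0,6.4,ypT0,ypN0,0,true,false,false,17.1,false,10.7,false,17.1,false,17.1
R6,rectum,52,female,0,no,T3,false,middle rectum,TORI,mutant,wild,wild,true,8,0,5.5,ypT0,ypN0,0,true,false,false,14.3,false,8.8,false,14.3,false,14.3
R7,rectum,33,female,0,no,T3,true,lower rectum,TORI+IRI+BEV,mutant,wild,wild,false,12,0,NA,NA,NA,NA,NA,true,true,9.0,true,NA,NA,12.4,false,12.4
R8,rectum,70,female,1,yes,T3,true,lower rectum,TORI,mutant,wild,wild,false,12,0,NA,NA,NA,NA,NA,true,true,8.8,false,NA,NA,8.8,false,8.8
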