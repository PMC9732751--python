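arm,variable,statistic,value
telemedicine,treatment_duration,n,26
telemedicine,treatment_duration,mean,8.23
telemedicine,treatment_duration,sd,4.45
telemedicine,treatment_duration,median,6.0
telemedicine,treatment_duration,q1,5.0
telemedicine,treatment_duration,q3,10.0
telemedicine,one_way_distance,n,26
telemedicine,one_way_distance,mean,37.0
telemedicine,one_way_distance,sd,32.06
telemedicine,one_way_distance,median,30.0
telemedicine,one_way_distance,q1,10.0
telemedicine,one_way_distance,q3,46.25
telemedicine,travel_time,n,26
telemedicine,travel_time,mean,38.46
telemedicine,travel_time,sd,21.72
telemedicine,travel_time,median,40.0
telemedicine,travel_time,q1,18.75
telemedicine,travel_time,q3,46.25
telemedicine,waiting_time,n,26
telemedicine,waiting_time,mean,6.73
telemedicine,waiting_time,sd,6.84
telemedicine,waiting_time,median,5.0
telemedicine,waiting_time,q1,1.75
telemedicine,waiting_time,q3,10.0
telemedicine,total_time,n,26
telemedicine,total_time,mean,21.92
telemedicine,total_time,sd,10.4
telemedicine,total_time,median,22.5
telemedicine,total_time,q1,13.75
telemedicine,total_time,q3,30.0
telemedicine,employment,n_records,26
telemedicine,employment,n_employed_known,26
telemedicine,employment,n_employed,20
telemedicine,employment,n_absent,1
control,treatment_duration,n,25
control,treatment_duration,mean,10.92
control,treatment_duration,sd,5.58
control,treatment_duration,median,10.0
control,treatment_duration,q1,8.0
control,treatment_duration,q3,14.5
control,one_way_distance,n,25
control,one_way_distance,mean,31.58
control,one_way_distance,sd,22.62
control,one_way_distance,median,28.0
control,one_way_distance,q1,15.5
control,one_way_distance,q3,45.0
control,travel_time,n,25
control,travel_time,mean,34.8
control,travel_time,sd,20.89
control,travel_time,median,30.0
control,travel_time,q1,20.0
control,travel_time,q3,40.0
control,waiting_time,n,24
control,waiting_time,mean,36.88
control,waiting_time,sd,27.54
control,waiting_time,median,30.0
control,waiting_time,q1,15.0
control,waiting_time,q3,48.75
control,total_time,n,25
control,total_time,mean,154.8
control,total_time,sd,79.75
control,total_time,median,150.0
control,total_time,q1,105.0
control,total_time,q3,197.5
control,employment,n_records,26
control,employment,n_employed_known,25
control,employment,n_employed,19
control,employment,n_absent,3
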