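# Published video-vs-IMU total TUG times with fall-risk categories,
# 12 older adults (59-93 y). rof = risk-of-falling label assigned from each
# method's total time (no / low / high). Values as printed.
subject,height_cm,weight_kg,age_years,gender,video_time_s,video_rof,imu_time_s,imu_rof
1,168,75,60,male,11.00,low,10.51,low
2,168,72,60,male,9.63,no,8.98,no
3,156,90,63,male,10.73,low,10.57,low
4,170,68,65,male,9.76,no,9.59,no
5,179,64,71,male,12.00,low,11.95,low
6,157,62,60,female,13.76,low,13.13,low
7,178,93,67,male,9.36,no,9.27,no
8,160,51,63,female,9.03,no,8.87,no
9,145,70,59,female,10.43,low,9.92,no
10,173,84,59,male,10.60,low,10.23,low
11,160,68,59,female,9.33,low,9.44,low
12,157,61,93,female,43,high,42.99,high
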