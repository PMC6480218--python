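# Published video-vs-IMU total TUG times, 25 healthy young adults (25-33 y).
# video_time_s: mean of two frame-by-frame video raters; imu_time_s: the
# automatic single-IMU segmentation. Values as printed, 2 decimals.
subject,height_cm,weight_kg,age_years,gender,video_time_s,imu_time_s
1,179,93,25,male,10.46,10.26
2,168,70,25,male,10.73,10.56
3,176,81,28,male,10.66,10.52
4,164,68,26,female,8.60,8.24
5,160,68,25,female,8.63,8.43
6,162,70,29,male,8.00,7.92
7,168,80,26,female,10.40,9.83
8,152,48,25,female,10.16,9.29
9,195,90,26,female,10.30,10.01
10,190,80,29,male,10.66,10.63
11,169,68,29,male,10.60,10.62
12,153,77,27,male,10.60,10.61
13,160,73,33,female,10.93,10.76
14,172,81,31,female,10.26,10.09
15,168,70,26,male,10.50,10.38
16,173,79,28,male,10.46,10.40
17,170,73,25,male,10.50,10.36
18,163,60,32,male,8.86,8.83
19,175,70,28,male,8.83,8.72
20,171,68,33,male,9.06,8.98
21,165,70,32,male,8.36,8.18
22,179,73,26,male,10.10,9.94
23,185,79,26,male,9.16,8.99
24,190,83,30,male,10.33,10.33
25,160,58,29,male,10.30,9.99
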