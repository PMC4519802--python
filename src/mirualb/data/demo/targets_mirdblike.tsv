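miR-t0	GENE011	mirdblike
miR-t0	GENE013	mirdblike
miR-t0	GENE027	mirdblike
miR-t0	GENE031	mirdblike
miR-t0	GENE085	mirdblike
miR-t1	GENE018	mirdblike
miR-t1	GENE032	mirdblike
miR-t1	GENE033	mirdblike
miR-t1	GENE035	mirdblike
miR-t1	GENE038	mirdblike
miR-t1	GENE053	mirdblike
miR-t1	GENE058	mirdblike
miR-t1	GENE059	mirdblike
miR-t1	GENE061	mirdblike
miR-t1	GENE067	mirdblike
miR-t1	GENE071	mirdblike
miR-t1	GENE075	mirdblike
miR-t1	GENE078	mirdblike
miR-t1	GENE084	mirdblike
miR-t1	GENE085	mirdblike
miR-t1	GENE090	mirdblike
miR-t1	GENE092	mirdblike
miR-t1	GENE097	mirdblike
miR-t2	GENE001	mirdblike
miR-t2	GENE011	mirdblike
miR-t2	GENE016	mirdblike
miR-t2	GENE024	mirdblike
miR-t2	GENE027	mirdblike
miR-t2	GENE042	mirdblike
miR-t2	GENE049	mirdblike
miR-t2	GENE052	mirdblike
miR-t2	GENE089	mirdblike
miR-t2	GENE090	mirdblike
miR-t2	GENE097	mirdblike
miR-t2	GENE098	mirdblike
miR-t2	GENE099	mirdblike
miR-t3	GENE004	mirdblike
miR-t3	GENE005	mirdblike
miR-t3	GENE013	mirdblike
miR-t3	GENE067	mirdblike
miR-t3	GENE077	mirdblike
miR-t3	GENE079	mirdblike
miR-t4	GENE003	mirdblike
miR-t4	GENE008	mirdblike
miR-t4	GENE010	mirdblike
miR-t4	GENE011	mirdblike
miR-t4	GENE014	mirdblike
miR-t4	GENE019	mirdblike
miR-t4	GENE021	mirdblike
miR-t4	GENE027	mirdblike
miR-t4	GENE032	mirdblike
miR-t4	GENE035	mirdblike
miR-t4	GENE045	mirdblike
miR-t4	GENE046	mirdblike
miR-t4	GENE049	mirdblike
miR-t4	GENE052	mirdblike
miR-t4	GENE053	mirdblike
miR-t4	GENE058	mirdblike
miR-t4	GENE070	mirdblike
miR-t4	GENE082	mirdblike
miR-t4	GENE089	mirdblike
miR-t4	GENE096	mirdblike
miR-t5	GENE014	mirdblike
miR-t5	GENE015	mirdblike
miR-t5	GENE016	mirdblike
miR-t5	GENE035	mirdblike
miR-t5	GENE038	mirdblike
miR-t5	GENE046	mirdblike
miR-t5	GENE068	mirdblike
miR-t5	GENE069	mirdblike
miR-t5	GENE097	mirdblike
miR-t6	GENE004	mirdblike
miR-t6	GENE006	mirdblike
miR-t6	GENE007	mirdblike
miR-t6	GENE016	mirdblike
miR-t6	GENE017	mirdblike
miR-t6	GENE020	mirdblike
miR-t6	GENE022	mirdblike
miR-t6	GENE025	mirdblike
miR-t6	GENE026	mirdblike
miR-t6	GENE027	mirdblike
miR-t6	GENE033	mirdblike
miR-t6	GENE035	mirdblike
miR-t6	GENE038	mirdblike
miR-t6	GENE046	mirdblike
miR-t6	GENE053	mirdblike
miR-t6	GENE057	mirdblike
miR-t6	GENE069	mirdblike
miR-t6	GENE072	mirdblike
miR-t6	GENE077	mirdblike
miR-t6	GENE081	mirdblike
miR-t6	GENE085	mirdblike
miR-t6	GENE094	mirdblike
miR-t6	GENE098	mirdblike
miR-t7	GENE000	mirdblike
miR-t7	GENE001	mirdblike
miR-t7	GENE005	mirdblike
miR-t7	GENE007	mirdblike
miR-t7	GENE021	mirdblike
miR-t7	GENE026	mirdblike
miR-t7	GENE028	mirdblike
miR-t7	GENE034	mirdblike
miR-t7	GENE037	mirdblike
miR-t7	GENE038	mirdblike
miR-t7	GENE044	mirdblike
miR-t7	GENE047	mirdblike
miR-t7	GENE049	mirdblike
miR-t7	GENE053	mirdblike
miR-t7	GENE064	mirdblike
miR-t7	GENE070	mirdblike
miR-t7	GENE072	mirdblike
miR-t7	GENE073	mirdblike
miR-t7	GENE074	mirdblike
miR-t7	GENE076	mirdblike
miR-t7	GENE082	mirdblike
miR-t8	GENE031	mirdblike
miR-t8	GENE049	mirdblike
miR-t8	GENE053	mirdblike
miR-t8	GENE054	mirdblike
miR-t8	GENE057	mirdblike
miR-t8	GENE060	mirdblike
miR-t8	GENE062	mirdblike
miR-t8	GENE075	mirdblike
miR-t8	GENE087	mirdblike
miR-t9	GENE013	mirdblike
miR-t9	GENE015	mirdblike
miR-t9	GENE016	mirdblike
miR-t9	GENE017	mirdblike
miR-t9	GENE040	mirdblike
miR-t9	GENE045	mirdblike
miR-t9	GENE050	mirdblike
miR-t9	GENE052	mirdblike
miR-t9	GENE057	mirdblike
miR-t9	GENE059	mirdblike
miR-t9	GENE070	mirdblike
miR-t9	GENE080	mirdblike
miR-t9	GENE085	mirdblike
miR-t10	GENE009	mirdblike
miR-t10	GENE013	mirdblike
miR-t10	GENE015	mirdblike
miR-t10	GENE024	mirdblike
miR-t10	GENE038	mirdblike
miR-t10	GENE050	mirdblike
miR-t10	GENE058	mirdblike
miR-t10	GENE060	mirdblike
miR-t10	GENE064	mirdblike
miR-t10	GENE076	mirdblike
miR-t10	GENE077	mirdblike
miR-t10	GENE088	mirdblike
miR-t10	GENE097	mirdblike
miR-t11	GENE006	mirdblike
miR-t11	GENE014	mirdblike
miR-t11	GENE015	mirdblike
miR-t11	GENE040	mirdblike
miR-t11	GENE043	mirdblike
miR-t11	GENE046	mirdblike
miR-t11	GENE047	mirdblike
miR-t11	GENE050	mirdblike
miR-t11	GENE057	mirdblike
miR-t11	GENE072	mirdblike
miR-t11	GENE073	mirdblike
miR-t11	GENE082	mirdblike
miR-t11	GENE084	mirdblike
miR-t11	GENE093	mirdblike
miR-t12	GENE001	mirdblike
miR-t12	GENE016	mirdblike
miR-t12	GENE023	mirdblike
miR-t12	GENE028	mirdblike
miR-t12	GENE046	mirdblike
miR-t12	GENE048	mirdblike
miR-t12	GENE053	mirdblike
miR-t12	GENE072	mirdblike
miR-t12	GENE080	mirdblike
miR-t12	GENE084	mirdblike
miR-t13	GENE004	mirdblike
miR-t13	GENE012	mirdblike
miR-t13	GENE021	mirdblike
miR-t13	GENE026	mirdblike
miR-t13	GENE061	mirdblike
miR-t13	GENE082	mirdblike
miR-t13	GENE091	mirdblike
miR-t13	GENE092	mirdblike
miR-t14	GENE003	mirdblike
miR-t14	GENE020	mirdblike
miR-t14	GENE023	mirdblike
miR-t14	GENE024	mirdblike
miR-t14	GENE030	mirdblike
miR-t14	GENE039	mirdblike
miR-t14	GENE041	mirdblike
miR-t14	GENE070	mirdblike
miR-t14	GENE072	mirdblike
miR-t14	GENE074	mirdblike
miR-t14	GENE086	mirdblike
miR-t14	GENE098	mirdblike
miR-t15	GENE012	mirdblike
miR-t15	GENE014	mirdblike
miR-t15	GENE027	mirdblike
miR-t15	GENE039	mirdblike
miR-t15	GENE040	mirdblike
miR-t15	GENE047	mirdblike
miR-t15	GENE055	mirdblike
miR-t15	GENE064	mirdblike
miR-t15	GENE069	mirdblike
miR-t15	GENE073	mirdblike
miR-t15	GENE081	mirdblike
miR-t15	GENE086	mirdblike
miR-t15	GENE087	mirdblike
miR-t16	GENE002	mirdblike
miR-t16	GENE003	mirdblike
miR-t16	GENE006	mirdblike
miR-t16	GENE007	mirdblike
miR-t16	GENE027	mirdblike
miR-t16	GENE031	mirdblike
miR-t16	GENE034	mirdblike
miR-t16	GENE044	mirdblike
miR-t16	GENE046	mirdblike
miR-t16	GENE054	mirdblike
miR-t16	GENE056	mirdblike
miR-t16	GENE068	mirdblike
miR-t16	GENE080	mirdblike
miR-t16	GENE082	mirdblike
miR-t16	GENE086	mirdblike
miR-t16	GENE089	mirdblike
miR-t16	GENE092	mirdblike
miR-t16	GENE098	mirdblike
miR-t16	GENE099	mirdblike
miR-t17	GENE019	mirdblike
miR-t17	GENE023	mirdblike
miR-t17	GENE027	mirdblike
miR-t17	GENE035	mirdblike
miR-t17	GENE038	mirdblike
miR-t17	GENE040	mirdblike
miR-t17	GENE045	mirdblike
miR-t17	GENE063	mirdblike
miR-t17	GENE064	mirdblike
miR-t17	GENE074	mirdblike
miR-t17	GENE085	mirdblike
miR-t17	GENE087	mirdblike
miR-t17	GENE091	mirdblike
miR-t17	GENE098	mirdblike
miR-t18	GENE004	mirdblike
miR-t18	GENE005	mirdblike
miR-t18	GENE037	mirdblike
miR-t18	GENE045	mirdblike
miR-t18	GENE054	mirdblike
miR-t18	GENE066	mirdblike
miR-t18	GENE071	mirdblike
miR-t18	GENE078	mirdblike
miR-t19	GENE010	mirdblike
miR-t19	GENE018	mirdblike
miR-t19	GENE025	mirdblike
miR-t19	GENE026	mirdblike
miR-t19	GENE029	mirdblike
miR-t19	GENE030	mirdblike
miR-t19	GENE034	mirdblike
miR-t19	GENE046	mirdblike
miR-t19	GENE061	mirdblike
miR-t19	GENE062	mirdblike
miR-t19	GENE068	mirdblike
miR-t19	GENE075	mirdblike
miR-t19	GENE092	mirdblike
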